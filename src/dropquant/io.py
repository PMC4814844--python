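"""File formats and run configuration.

Amplitude CSVs mirror the droplet-reader export: a header line
``Ch1 Amplitude,Ch2 Amplitude`` and one droplet per row.  Cluster counts,
per-droplet labels, quantification results and study tables are plain
CSV/JSON; run configuration is YAML.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .gating import CLUSTER_LABELS, ClusterCounts, GateConfig
from .quantify import QuantEstimate
from .simulate import DEFAULT_DROPLET_VOLUME_NL, GENOME_COPIES_PER_NG, WellData

__all__ = [
    "AMPLITUDE_HEADER",
    "read_amplitude_csv",
    "write_amplitude_csv",
    "read_cluster_counts_csv",
    "write_cluster_counts_csv",
    "write_labels_csv",
    "quant_to_record",
    "write_results",
    "load_gates",
    "dump_gates",
    "RunConfig",
]

AMPLITUDE_HEADER = ("Ch1 Amplitude", "Ch2 Amplitude")
_COUNT_FIELDS = ("n_empty", "n_nhej", "n_wt_plus", "n_hdr_plus", "n_anomalous")


def read_amplitude_csv(path, well_id: str | None = None,
                       truth_path=None) -> WellData:
    """Read a two-channel amplitude CSV into a WellData.

    The file must start with the ``Ch1 Amplitude,Ch2 Amplitude`` header and
    contain one numeric row per droplet.  Malformed rows are reported with
    their line number.  A truth sidecar (columns wt,hdr,nhej) written by the
    simulator can be re-attached via ``truth_path``.
    """
    path = Path(path)
    ch1, ch2 = [], []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
        if tuple(h.strip() for h in header[:2]) != AMPLITUDE_HEADER:
            raise ValueError(
                f"{path}: expected header {','.join(AMPLITUDE_HEADER)!r}, "
                f"got {','.join(header)!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            try:
                ch1.append(float(row[0]))
                ch2.append(float(row[1]))
            except (ValueError, IndexError):
                raise ValueError(
                    f"{path}: malformed row at line {lineno}: {','.join(row)!r}"
                ) from None
    if not ch1:
        raise ValueError(f"{path}: no droplet rows")
    truth = None
    if truth_path is not None:
        tdf = pd.read_csv(truth_path)
        truth = tdf[["wt", "hdr", "nhej"]].to_numpy(dtype=int)
    return WellData(
        well_id=well_id or path.stem,
        ch1=np.array(ch1),
        ch2=np.array(ch2),
        truth=truth,
    )


def write_amplitude_csv(well: WellData, path, truth_path=None) -> None:
    """Write a WellData as an amplitude CSV (plus optional truth sidecar)."""
    df = pd.DataFrame({AMPLITUDE_HEADER[0]: well.ch1, AMPLITUDE_HEADER[1]: well.ch2})
    df.to_csv(path, index=False)
    if truth_path is not None:
        if well.truth is None:
            raise ValueError("well carries no truth occupancy to write")
        pd.DataFrame(well.truth, columns=["wt", "hdr", "nhej"]).to_csv(
            truth_path, index=False
        )


def write_cluster_counts_csv(counts_by_well: dict[str, ClusterCounts], path) -> None:
    rows = [{"well_id": wid, **{f: getattr(c, f) for f in _COUNT_FIELDS}}
            for wid, c in counts_by_well.items()]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_cluster_counts_csv(path) -> dict[str, ClusterCounts]:
    df = pd.read_csv(path)
    missing = [c for c in ("well_id", *_COUNT_FIELDS[:4]) if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    out = {}
    for _, row in df.iterrows():
        out[str(row["well_id"])] = ClusterCounts(
            int(row["n_empty"]), int(row["n_nhej"]), int(row["n_wt_plus"]),
            int(row["n_hdr_plus"]), int(row.get("n_anomalous", 0) or 0),
        )
    return out


def write_labels_csv(well: WellData, labels: np.ndarray, path) -> None:
    pd.DataFrame({
        AMPLITUDE_HEADER[0]: well.ch1,
        AMPLITUDE_HEADER[1]: well.ch2,
        "cluster": [CLUSTER_LABELS[i] for i in labels],
    }).to_csv(path, index=False)


def quant_to_record(est: QuantEstimate, sample_id: str = "",
                    round_percent: int | None = None) -> dict:
    """Flatten a QuantEstimate into one results-table row.

    Percentages are stored at full precision unless ``round_percent`` asks
    for display rounding.
    """
    rec: dict = {"sample_id": sample_id}
    for cls in ("wt", "hdr", "nhej"):
        ce = getattr(est, cls)
        rec[f"lambda_{cls}"] = ce.rate.lam
        rec[f"ci_low_{cls}"] = ce.rate.ci_low
        rec[f"ci_high_{cls}"] = ce.rate.ci_high
        rec[f"copies_{cls}"] = ce.copies
        rec[f"conc_{cls}_per_ul"] = ce.concentration
        freq = ce.frequency
        rec[f"freq_{cls}_pct"] = round(freq, round_percent) if round_percent is not None else freq
    for f in _COUNT_FIELDS:
        rec[f] = getattr(est.counts, f)
    rec["droplet_volume_nl"] = est.droplet_volume_nl
    return rec


def write_results(records: list[dict], path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(records, indent=2, default=float) + "\n")
    else:
        pd.DataFrame(records).to_csv(path, index=False)


def load_gates(path) -> GateConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return GateConfig(
        fam_low=float(data["fam_low"]),
        fam_high=float(data["fam_high"]),
        hex_low=float(data["hex_low"]),
    )


def dump_gates(gates: GateConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump({
        "fam_low": float(gates.fam_low),
        "fam_high": float(gates.fam_high),
        "hex_low": float(gates.hex_low),
    }))


@dataclass
class RunConfig:
    """Structured configuration for a pipeline run (YAML on disk).

    CLI flags override config keys; percentages are kept at full precision
    internally and rounded only for display.
    """

    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL
    genome_copies_per_ng: float = GENOME_COPIES_PER_NG
    n_droplets: int = 15_000
    seed: int = 0
    gates: dict | None = None  # fam_low/fam_high/hex_low
    fit_gates_from: dict | None = None  # {'negative': path, 'positive': path}
    display_decimals: int = 1
    out_dir: str = "."
    simulate: dict | None = None  # rates or copies+fractions, model overrides
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.droplet_volume_nl <= 0:
            raise ValueError("droplet volume must be positive")
        if self.n_droplets < 1:
            raise ValueError("n_droplets must be >= 1")
        self.seed = int(self.seed)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        kwargs = {k: v for k, v in data.items() if k in known}
        extra = {k: v for k, v in data.items() if k not in known}
        return cls(**kwargs, extra=extra)

    def to_yaml(self, path) -> None:
        data = {k: v for k, v in vars(self).items() if k != "extra" and v is not None}
        data.update(self.extra)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    def gate_config(self) -> GateConfig | None:
        if self.gates is None:
            return None
        return GateConfig(
            fam_low=float(self.gates["fam_low"]),
            fam_high=float(self.gates["fam_high"]),
            hex_low=float(self.gates["hex_low"]),
        )
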