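"""Tissue-residue summaries and the exposure calculus.

Whole-body composite contaminant concentrations (ng/g lipid) measured in
outmigrating juvenile Chinook salmon at sites within, upstream of, and
downstream of Portland Harbor, together with the arithmetic used to reason
about them: lipid normalization, between-site fold changes, and exceedance
of sublethal-effect thresholds (2,400 ng/g lipid for PCBs, 6,000 ng/g lipid
for DDTs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "ResidueRecord",
    "EffectThreshold",
    "DEFAULT_THRESHOLDS",
    "lipid_normalize",
    "fold_change",
    "exceeds_threshold",
    "load_residue_table",
    "bundled_residue_table",
]

ANALYTES = ("PCBs", "DDTs", "PAHs", "TBT")
BANKS = ("east", "west", "downstream", "upstream")


@dataclass(frozen=True)
class ResidueRecord:
    """Mean contaminant concentration for one site x analyte combination."""

    site: str
    analyte: str
    mean_concentration: float  # ng/g lipid
    n_composites: int = 1
    sd: float | None = None  # ng/g lipid
    bank: str | None = None
    year: int | None = None

    def __post_init__(self) -> None:
        if self.analyte not in ANALYTES:
            raise ValueError(f"analyte must be one of {ANALYTES}, got {self.analyte!r}")
        if self.mean_concentration < 0:
            raise ValueError(
                f"mean_concentration must be >= 0, got {self.mean_concentration!r}"
            )
        if self.n_composites < 1:
            raise ValueError(f"n_composites must be >= 1, got {self.n_composites!r}")
        if self.bank is not None and self.bank not in BANKS:
            raise ValueError(f"bank must be one of {BANKS}, got {self.bank!r}")


@dataclass(frozen=True)
class EffectThreshold:
    """A lipid-normalized concentration above which sublethal effects are
    expected."""

    analyte: str
    value: float  # ng/g lipid
    basis: str = ""

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise ValueError(f"threshold value must be > 0, got {self.value!r}")


#: Sublethal-effect thresholds for juvenile salmonids, ng/g lipid.
DEFAULT_THRESHOLDS = {
    "PCBs": EffectThreshold("PCBs", 2400.0, basis="adverse sublethal effects in juvenile salmonids"),
    "DDTs": EffectThreshold("DDTs", 6000.0, basis="600 ng/g wet weight at 10% lipid"),
}


def lipid_normalize(wet_weight_conc: float, percent_lipid: float) -> float:
    """Convert a wet-weight concentration (ng/g) to ng/g lipid."""
    if not percent_lipid > 0:
        raise ValueError(f"percent_lipid must be > 0, got {percent_lipid!r}")
    if wet_weight_conc < 0:
        raise ValueError(f"wet_weight_conc must be >= 0, got {wet_weight_conc!r}")
    return wet_weight_conc / (percent_lipid / 100.0)


def fold_change(conc_a: float, conc_b: float) -> float:
    """Ratio of two concentrations (how many fold ``conc_a`` exceeds
    ``conc_b``)."""
    if not conc_b > 0:
        raise ValueError(f"denominator concentration must be > 0, got {conc_b!r}")
    return conc_a / conc_b


def exceeds_threshold(
    record: ResidueRecord, threshold: EffectThreshold
) -> tuple[bool, float]:
    """Whether a record strictly exceeds an effect threshold, and by what
    ratio."""
    if record.analyte != threshold.analyte:
        raise ValueError(
            f"analyte mismatch: record is {record.analyte!r}, "
            f"threshold is {threshold.analyte!r}"
        )
    ratio = record.mean_concentration / threshold.value
    return record.mean_concentration > threshold.value, ratio


_COLUMNS = ["site", "analyte", "mean_ng_g_lipid", "sd", "n", "bank", "year"]


def load_residue_table(path: str | Path) -> list[ResidueRecord]:
    """Read a residue CSV (site, analyte, mean_ng_g_lipid, sd, n, bank, year)
    into validated records."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = set(_COLUMNS[:3]) - set(df.columns)
    if missing:
        raise ValueError(f"{path} is missing required columns: {sorted(missing)}")
    if df.empty:
        warnings.warn(f"{path} contains no residue records", stacklevel=2)
        return []
    records = []
    for idx, row in df.iterrows():
        try:
            records.append(
                ResidueRecord(
                    site=str(row["site"]),
                    analyte=str(row["analyte"]),
                    mean_concentration=float(row["mean_ng_g_lipid"]),
                    n_composites=int(row["n"]) if pd.notna(row.get("n")) else 1,
                    sd=float(row["sd"]) if pd.notna(row.get("sd")) else None,
                    bank=str(row["bank"]) if pd.notna(row.get("bank")) else None,
                    year=int(row["year"]) if pd.notna(row.get("year")) else None,
                )
            )
        except (ValueError, TypeError) as exc:
            # +2: header line plus 1-based indexing
            raise ValueError(f"{path}, line {idx + 2}: {exc}") from exc
    return records


def bundled_residue_table() -> list[ResidueRecord]:
    """The DDT site means shipped with the package (ng/g lipid)."""
    ref = resources.files("chinook_pva.data").joinpath("tissue_residues.csv")
    with resources.as_file(ref) as path:
        return load_residue_table(path)
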