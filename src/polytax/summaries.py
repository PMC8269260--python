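"""Collection-level tallies, novelty counting and qPCR normalization.

Operates on a culture-collection table (one row per isolate with taxonomy
and the best-hit 16S identity against a reference database). Percentages
are rounded half-up to one decimal, matching how such tallies are
conventionally reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from importlib import resources
from pathlib import Path
from typing import Optional

import pandas as pd

REQUIRED_COLUMNS = [
    "isolate_id", "species_name", "genus", "family", "phylum",
    "best_hit_identity", "is_syn_member",
]

_LEVELS = ("phylum", "family")


def load_collection(path: Optional[str | Path] = None) -> pd.DataFrame:
    """Load a collection table (tab-separated; '#' lines are comments).

    Without a path, loads the packaged 43-isolate chicken gut collection
    stand-in (see data/collection_s1_synthetic.tsv for its provenance).
    """
    if path is None:
        ref = resources.files("polytax.data") / "collection_s1_synthetic.tsv"
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t", comment="#")
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"collection table missing columns: {missing}")
    if df.empty:
        raise ValueError("collection table is empty")
    bad = df[(df.best_hit_identity < 0) | (df.best_hit_identity > 100)]
    if not bad.empty:
        raise ValueError("best_hit_identity outside [0, 100]")
    for col in ("species_name", "genus", "family", "phylum"):
        if df[col].isna().any() or (df[col].astype(str).str.strip() == "").any():
            raise ValueError(f"empty values in taxonomy column {col!r}")
    return df


def round_half_up(value: float, decimals: int = 1) -> float:
    """Round half away from zero, the convention of printed percentage tables."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class TaxonTally:
    level: str
    counts: dict[str, int]
    percentages: dict[str, float]
    total: int


@dataclass(frozen=True)
class QpcrResult:
    gene: str
    ct_target: float
    ct_reference: float

    @property
    def dct(self) -> float:
        return self.ct_target - self.ct_reference

    @property
    def relative_expression(self) -> float:
        return 40.0 - self.dct


def tally_collection(table: pd.DataFrame, level: str) -> TaxonTally:
    """Counts and half-up-rounded percentages per taxon at phylum/family level."""
    if level not in _LEVELS:
        raise ValueError(f"unknown tally level {level!r}; use one of {_LEVELS}")
    counts_series = table[level].value_counts()
    total = int(len(table))
    counts = {str(k): int(v) for k, v in counts_series.items()}
    percentages = {k: round_half_up(100.0 * v / total) for k, v in counts.items()}
    return TaxonTally(level=level, counts=counts, percentages=percentages,
                      total=total)


def count_novel(table: pd.DataFrame, threshold: float = 98.7) -> int:
    """Isolates whose best 16S hit is at or below the species threshold.

    The rule is inclusive: an identity of exactly the threshold counts as
    potentially novel.
    """
    return int((table["best_hit_identity"] <= threshold).sum())


def qpcr_relative_expression(ct_target: float, ct_reference: float,
                             gene: str = "") -> QpcrResult:
    """dCT normalization against a housekeeping gene, on a 40-cycle run.

    relative expression = 40 - (ct_target - ct_reference); higher means more
    transcript. Cycle values must lie in [0, 40].
    """
    for name, ct in (("ct_target", ct_target), ("ct_reference", ct_reference)):
        if not 0.0 <= ct <= 40.0:
            raise ValueError(f"{name}={ct} outside the cycle range [0, 40]")
    return QpcrResult(gene=gene, ct_target=ct_target, ct_reference=ct_reference)
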