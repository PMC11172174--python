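"""Per-TE-family piRNA quantification and silencing-potential calls.

A TE family's piRNA pool is summarized as sense and antisense rpm per
genotype (reads mapped one-best with up to 3 mismatches, normalized to
the pre-miRNA-filtration depth). The silencing-potential call is binary:
a genotype can silence a family when its antisense TE-mapped piRNAs
exceed 100 rpm (strict). Fold reductions compare parental to hybrid
antisense rpm; classification uses unrounded ratios (inclusive at the
fivefold boundary) while reported folds are rounded half-up to one
decimal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import pandas as pd

from .align import AlignmentRecord, strand_of_te_read
from .smallrna import ReadLibrary, rpm

__all__ = [
    "SILENCING_RPM_THRESHOLD",
    "TEPiRNAProfile",
    "count_te_pirnas",
    "silencing_potential",
    "fold_reduction",
    "profiles_from_rpm_table",
    "cohort_summary",
]

SILENCING_RPM_THRESHOLD = 100.0
FIVEFOLD = 5.0


@dataclass
class TEPiRNAProfile:
    """Sense/antisense piRNA rpm per genotype for one TE family."""

    family: str
    te_class: str = "LTR"
    sense_rpm: dict[str, float] = field(default_factory=dict)
    antisense_rpm: dict[str, float] = field(default_factory=dict)

    def silencing_ok(self, genotype: str, threshold: float = SILENCING_RPM_THRESHOLD) -> bool:
        return silencing_potential(self.antisense_rpm[genotype], threshold)

    def fold_reduction_vs(self, parent: str, hybrid: str = "hybrid") -> float | None:
        """Rounded parent/hybrid antisense ratio; None when undefined."""
        return fold_reduction(self.antisense_rpm[parent], self.antisense_rpm[hybrid])

    def raw_ratio_vs(self, parent: str, hybrid: str = "hybrid") -> float | None:
        h = self.antisense_rpm[hybrid]
        if h <= 0:
            return None
        return self.antisense_rpm[parent] / h


def count_te_pirnas(
    alignments: Sequence[AlignmentRecord],
    lib: ReadLibrary,
    te_panel: Mapping[str, str],
    weights: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Per-family sense/antisense read counts and rpm.

    ``alignments`` should come from TE-mode mapping (one placement per
    read, <= 3 mismatches); ``te_panel`` maps family name -> TE class.
    Returns a DataFrame indexed by family with columns
    sense_count/antisense_count/sense_rpm/antisense_rpm/te_class.
    """
    counts: dict[str, dict[str, float]] = {
        fam: {"sense": 0.0, "antisense": 0.0} for fam in te_panel
    }
    for rec in alignments:
        if rec.ref_id not in counts:
            raise ValueError(f"alignment to unknown TE family {rec.ref_id!r}")
        w = 1.0 if weights is None else float(weights.get(rec.read_id, 1.0))
        counts[rec.ref_id][strand_of_te_read(rec)] += w
    rows = {
        fam: {
            "te_class": te_panel[fam],
            "sense_count": c["sense"],
            "antisense_count": c["antisense"],
            "sense_rpm": rpm(c["sense"], lib),
            "antisense_rpm": rpm(c["antisense"], lib),
        }
        for fam, c in counts.items()
    }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "family"
    return df


def silencing_potential(
    antisense_rpm: float, threshold: float = SILENCING_RPM_THRESHOLD
) -> bool:
    """True iff antisense rpm strictly exceeds the threshold (>100 rpm)."""
    if antisense_rpm < 0:
        raise ValueError("antisense rpm must be non-negative")
    return antisense_rpm > threshold


def fold_reduction(parent_rpm: float, hybrid_rpm: float) -> float | None:
    """parent/hybrid antisense rpm, rounded half-up to one decimal.

    Returns None (undefined) when the hybrid rpm is zero.
    """
    if parent_rpm < 0 or hybrid_rpm < 0:
        raise ValueError("rpm values must be non-negative")
    if hybrid_rpm == 0:
        return None
    ratio = Decimal(str(parent_rpm)) / Decimal(str(hybrid_rpm))
    return float(ratio.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def profiles_from_rpm_table(
    table: pd.DataFrame, te_classes: Mapping[str, str] | None = None
) -> list[TEPiRNAProfile]:
    """Build profiles from an antisense-rpm table (families x genotypes)."""
    profiles = []
    for fam, row in table.iterrows():
        profiles.append(
            TEPiRNAProfile(
                family=str(fam),
                te_class=(te_classes or {}).get(str(fam), "LTR"),
                antisense_rpm={g: float(v) for g, v in row.items()},
            )
        )
    return profiles


@dataclass(frozen=True)
class CohortSummary:
    n_reduced_vs_both: int
    n_reduced_vs_at_least_one: int
    reduced_vs_both: tuple[str, ...]
    reduced_vs_at_least_one: tuple[str, ...]
    silencing_pass: tuple[str, ...]
    silencing_fail: tuple[str, ...]


def cohort_summary(
    profiles: Sequence[TEPiRNAProfile],
    parents: tuple[str, str] = ("mel", "sim"),
    hybrid: str = "hybrid",
    fold_threshold: float = FIVEFOLD,
    rpm_threshold: float = SILENCING_RPM_THRESHOLD,
) -> CohortSummary:
    """Cohort-level counts over a set of TE profiles.

    A family counts as reduced vs a parent when the *unrounded*
    parent/hybrid antisense ratio is >= fold_threshold (an undefined
    ratio, hybrid rpm 0 with nonzero parent, counts as reduced).
    Membership lists preserve nothing of input order (sorted).
    """
    both: list[str] = []
    at_least_one: list[str] = []
    sil_pass: list[str] = []
    sil_fail: list[str] = []
    for prof in profiles:
        for p in parents:
            if p not in prof.antisense_rpm:
                raise ValueError(f"profile {prof.family}: missing parent {p!r}")
        flags = []
        for p in parents:
            ratio = prof.raw_ratio_vs(p, hybrid)
            if ratio is None:
                flags.append(prof.antisense_rpm[p] > 0)
            else:
                flags.append(ratio >= fold_threshold)
        if all(flags):
            both.append(prof.family)
        if any(flags):
            at_least_one.append(prof.family)
        if prof.silencing_ok(hybrid, rpm_threshold):
            sil_pass.append(prof.family)
        else:
            sil_fail.append(prof.family)
    return CohortSummary(
        n_reduced_vs_both=len(both),
        n_reduced_vs_at_least_one=len(at_least_one),
        reduced_vs_both=tuple(sorted(both)),
        reduced_vs_at_least_one=tuple(sorted(at_least_one)),
        silencing_pass=tuple(sorted(sil_pass)),
        silencing_fail=tuple(sorted(sil_fail)),
    )
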