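"""Editing quantification at predicted sites from CDS pileups.

For each (site, library) pair, the base of every aligned read overlapping
the site is classified as edited (T), unedited (C) or other (A/G/N). A site
is *detected* in a library when coverage >= 5 and the one-sided binomial
tail probability of seeing that many T's from sequencing error alone is
<= 1e-2; it is *selected* for the report when its total coverage across
libraries reaches the minimum (default 4) and it is detected in at least
one library. Control-vs-salt differences use a two-tailed equal-variance
t-test on per-library fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from scipy import stats as _scipy_stats

from chloredit._stats import TTestResult, benjamini_hochberg, two_sample_t
from chloredit.align_filter import CdsAlignment
from chloredit.synthetic_data import EditingSiteRecord

DEFAULT_MIN_COVERAGE = 5
DEFAULT_MAX_VARIANT_P = 1e-2
DEFAULT_MIN_TOTAL_COVERAGE = 4
DEFAULT_ERROR_RATE = 0.01


@dataclass(frozen=True)
class SitePileup:
    """Per-site, per-library base counts."""

    gene_id: str
    cds_position: int  # 1-based within the CDS
    library_id: str
    n_edited: int = 0  # T
    n_unedited: int = 0  # C
    n_other: int = 0  # A/G/N

    def __post_init__(self) -> None:
        if min(self.n_edited, self.n_unedited, self.n_other) < 0:
            raise ValueError("pileup counts must be >= 0")

    @property
    def coverage(self) -> int:
        return self.n_edited + self.n_unedited + self.n_other


@dataclass
class SiteEditingStats:
    """All per-site quantities feeding one report row."""

    site: EditingSiteRecord
    pileups: dict[str, SitePileup] = field(default_factory=dict)  # by library
    fractions: dict[str, float | None] = field(default_factory=dict)
    variant_p: dict[str, float] = field(default_factory=dict)
    detected: dict[str, bool] = field(default_factory=dict)
    comparison: TTestResult | None = None
    selected: bool = False

    @property
    def total_coverage(self) -> int:
        return sum(p.coverage for p in self.pileups.values())


def pileup_sites(
    alignments_by_library: Mapping[str, Sequence[CdsAlignment]],
    sites: Sequence[EditingSiteRecord],
    cds_set: Mapping[str, str],
) -> list[SitePileup]:
    """Count edited/unedited/other bases at each site in each library."""
    for s in sites:
        if s.gene_id not in cds_set:
            raise KeyError(f"site {s.gene_id}:{s.cds_position} on unknown CDS")
        if s.cds_position > len(cds_set[s.gene_id]):
            raise IndexError(
                f"site {s.gene_id}:{s.cds_position} beyond CDS length "
                f"{len(cds_set[s.gene_id])}"
            )

    sites_by_gene: dict[str, list[EditingSiteRecord]] = {}
    for s in sites:
        sites_by_gene.setdefault(s.gene_id, []).append(s)

    pileups: list[SitePileup] = []
    for lib_id, alignments in alignments_by_library.items():
        counts: dict[tuple[str, int], list[int]] = {
            (s.gene_id, s.cds_position): [0, 0, 0] for s in sites
        }
        for a in alignments:
            for s in sites_by_gene.get(a.gene_id, ()):
                off = s.cds_position - 1 - a.start
                if 0 <= off < len(a.sequence):
                    base = a.sequence[off]
                    c = counts[(s.gene_id, s.cds_position)]
                    if base == "T":
                        c[0] += 1
                    elif base == "C":
                        c[1] += 1
                    else:
                        c[2] += 1
        for s in sites:
            e, u, o = counts[(s.gene_id, s.cds_position)]
            pileups.append(SitePileup(s.gene_id, s.cds_position, lib_id, e, u, o))
    return pileups


def variant_test(
    pileup: SitePileup,
    error_rate: float = DEFAULT_ERROR_RATE,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    max_p: float = DEFAULT_MAX_VARIANT_P,
) -> tuple[float, bool]:
    """Upper-tail binomial test of n_edited among coverage at error_rate.

    Returns (p_value, detected); detected requires coverage >= min_coverage
    and p <= max_p.
    """
    if not 0.0 < error_rate < 0.5:
        raise ValueError("error_rate must lie in (0, 0.5)")
    n = pileup.coverage
    k = pileup.n_edited
    if n == 0 or k == 0:
        p = 1.0
    else:
        p = float(
            _scipy_stats.binomtest(k, n, error_rate, alternative="greater").pvalue
        )
    detected = n >= min_coverage and p <= max_p
    return p, detected


def editing_fraction(pileup: SitePileup) -> float | None:
    """n_edited / (n_edited + n_unedited); None ('nd') if the denominator is 0.

    A/G/N reads are excluded from the denominator: the report concerns the
    C-vs-T proportion only.
    """
    denom = pileup.n_edited + pileup.n_unedited
    if denom == 0:
        return None
    return pileup.n_edited / denom


def compare_conditions(
    fractions_by_library: Mapping[str, float | None],
    condition_by_library: Mapping[str, str],
    conditions: tuple[str, str] = ("control", "salt"),
) -> TTestResult:
    """Control-vs-salt t-test on per-library fractions ('nd' libraries excluded)."""
    groups: dict[str, list[float]] = {c: [] for c in conditions}
    for lib, frac in fractions_by_library.items():
        if frac is None:
            continue
        cond = condition_by_library[lib]
        if cond in groups:
            groups[cond].append(frac)
    return two_sample_t(groups[conditions[0]], groups[conditions[1]])


def compute_site_stats(
    pileups: Sequence[SitePileup],
    sites: Sequence[EditingSiteRecord],
    condition_by_library: Mapping[str, str],
    error_rate: float = DEFAULT_ERROR_RATE,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    max_p: float = DEFAULT_MAX_VARIANT_P,
) -> list[SiteEditingStats]:
    by_site: dict[tuple[str, int], SiteEditingStats] = {
        (s.gene_id, s.cds_position): SiteEditingStats(site=s) for s in sites
    }
    for p in pileups:
        st = by_site.get((p.gene_id, p.cds_position))
        if st is None:
            continue
        st.pileups[p.library_id] = p
        st.fractions[p.library_id] = editing_fraction(p)
        vp, det = variant_test(p, error_rate, min_coverage, max_p)
        st.variant_p[p.library_id] = vp
        st.detected[p.library_id] = det
    for st in by_site.values():
        st.comparison = compare_conditions(st.fractions, condition_by_library)
    return [by_site[(s.gene_id, s.cds_position)] for s in sites]


def select_sites(
    stats: Sequence[SiteEditingStats],
    min_total_coverage: int = DEFAULT_MIN_TOTAL_COVERAGE,
    library_order: Sequence[str] | None = None,
    bh_adjust: bool = False,
) -> pd.DataFrame:
    """Build the per-site report table and set the selected flag.

    selected <=> total coverage across libraries >= min_total_coverage AND
    detected in >= 1 library. Both the edited count and the total coverage
    are emitted per library (the two possible count conventions).
    """
    if library_order is None:
        seen: list[str] = []
        for st in stats:
            for lib in st.pileups:
                if lib not in seen:
                    seen.append(lib)
        library_order = seen

    rows = []
    for st in stats:
        st.selected = st.total_coverage >= min_total_coverage and any(
            st.detected.get(lib, False) for lib in library_order
        )
        row: dict[str, object] = {
            "gene_id": st.site.gene_id,
            "cds_position": st.site.cds_position,
            "score": st.site.score,
        }
        for lib in library_order:
            p = st.pileups.get(lib)
            frac = st.fractions.get(lib)
            row[f"{lib}_edited"] = p.n_edited if p else 0
            row[f"{lib}_coverage"] = p.coverage if p else 0
            row[f"{lib}_fraction"] = float("nan") if frac is None else round(frac, 2)
        cmp = st.comparison
        row["p_value"] = (
            float("nan") if cmp is None or cmp.p_value is None else cmp.p_value
        )
        row["degenerate"] = bool(cmp.degenerate) if cmp else True
        row["total_coverage"] = st.total_coverage
        row["selected"] = st.selected
        rows.append(row)

    columns = ["gene_id", "cds_position", "score"]
    for lib in library_order:
        columns += [f"{lib}_edited", f"{lib}_coverage", f"{lib}_fraction"]
    columns += ["p_value", "degenerate", "total_coverage", "selected"]
    df = pd.DataFrame(rows, columns=columns)
    df = df.sort_values(["gene_id", "cds_position"], kind="stable").reset_index(drop=True)
    if bh_adjust and len(df):
        df["q_value"] = benjamini_hochberg(df["p_value"].fillna(1.0))
    return df


def write_report(df: pd.DataFrame, path: str | Path) -> None:
    """Write the report TSV; undefined fractions appear as 'nd'."""
    out = df.copy()
    for col in out.columns:
        if col.endswith("_fraction"):
            out[col] = out[col].map(
                lambda v: "nd" if pd.isna(v) else f"{v:.2f}"
            )
    out.to_csv(path, sep="\t", index=False, na_rep="NA")
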