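"""Gene x library count table, median-of-ratios normalization, and a simple
per-gene differential test (two-sample t on log2 normalized counts with
Benjamini-Hochberg adjustment)."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats

from chloredit._stats import benjamini_hochberg
from chloredit.align_filter import CdsAlignment

logger = logging.getLogger(__name__)


@dataclass
class CountMatrix:
    counts: pd.DataFrame  # genes x libraries, integer
    size_factors: pd.Series | None = None
    normalized: pd.DataFrame | None = None


def build_count_table(
    alignments_by_library: Mapping[str, Sequence[CdsAlignment]],
    gene_ids: Sequence[str],
) -> CountMatrix:
    """Count each read once per library, toward the CDS of its first placement."""
    libs = list(alignments_by_library)
    counts = pd.DataFrame(0, index=list(gene_ids), columns=libs, dtype=int)
    for lib, alignments in alignments_by_library.items():
        if not alignments:
            logger.warning("library %s has zero alignments", lib)
            continue
        seen: set[str] = set()
        n_multi = 0
        for a in alignments:
            if a.read_id in seen:
                n_multi += 1
                continue
            seen.add(a.read_id)
            counts.loc[a.gene_id, lib] += 1
        if n_multi:
            logger.info(
                "library %s: %d multi-CDS placements ignored (first kept)", lib, n_multi
            )
    return CountMatrix(counts=counts)


def normalize_median_ratios(counts: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Median-of-ratios size factors over genes with all-positive counts.

    size_factor_j = median_i( count_ij / geomean_i ), geomean over libraries.
    """
    if (counts < 0).any().any():
        raise ValueError("counts must be non-negative")
    positive = counts[(counts > 0).all(axis=1)]
    if positive.empty:
        raise ValueError("no gene has positive counts in every library")
    geomean = np.exp(np.log(positive).mean(axis=1))
    size_factors = positive.div(geomean, axis=0).median(axis=0)
    normalized = counts.div(size_factors, axis=1)
    return size_factors, normalized


def differential_test(
    normalized: pd.DataFrame,
    groups: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Per-gene t-test on log2(normalized+1) between two library groups.

    Returns a DataFrame (gene, log2fc, p, q); log2fc is the second group's
    mean minus the first's, in ``groups`` insertion order.
    """
    if len(groups) != 2:
        raise ValueError("exactly two groups are required")
    (name_a, libs_a), (name_b, libs_b) = groups.items()
    for name, libs in ((name_a, libs_a), (name_b, libs_b)):
        if len(libs) == 0:
            raise ValueError(f"group {name!r} is empty")
        if len(libs) < 2:
            raise ValueError(f"group {name!r} needs >= 2 libraries")
        missing = [l for l in libs if l not in normalized.columns]
        if missing:
            raise KeyError(f"group {name!r} references unknown libraries {missing}")

    log_a = np.log2(normalized[list(libs_a)] + 1.0)
    log_b = np.log2(normalized[list(libs_b)] + 1.0)
    lfc = log_b.mean(axis=1) - log_a.mean(axis=1)

    stat, p = _scipy_stats.ttest_ind(log_a, log_b, axis=1, equal_var=True)
    p = np.asarray(p, dtype=float)
    # zero pooled variance: equal means -> p=1, different means -> p=0
    var_zero = np.isnan(p)
    p[var_zero & (np.asarray(lfc) == 0.0)] = 1.0
    p[var_zero & (np.asarray(lfc) != 0.0)] = 0.0

    df = pd.DataFrame(
        {"gene_id": normalized.index, "log2fc": lfc.values, "p_value": p}
    )
    df["q_value"] = benjamini_hochberg(df["p_value"])
    return df.reset_index(drop=True)


def write_heatmap_matrix(normalized: pd.DataFrame, path: str | Path) -> None:
    normalized.to_csv(path, sep="\t", float_format="%.4f")


def plot_heatmap(normalized: pd.DataFrame, path: str | Path) -> None:
    """Optional image output (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = np.log2(normalized + 1.0)
    fig, ax = plt.subplots(figsize=(6, max(3, 0.25 * len(data))))
    im = ax.imshow(data.values, aspect="auto", cmap="viridis")
    ax.set_xticks(range(len(data.columns)), data.columns, rotation=90)
    ax.set_yticks(range(len(data.index)), data.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="log2(normalized + 1)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
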