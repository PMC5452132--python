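"""Allele-specific qPCR analysis: Ct calling, window-of-linearity
efficiency estimation, efficiency filtering, and Ct-ratio editing-fraction
computation with treatment comparison.

The edited fraction of one sample is computed from the Ct values of its
T-specific and C-specific reactions as Q_T / (Q_T + Q_C) with
Q = efficiency^(-Ct), which reduces to 1 / (1 + 2^(ct_T - ct_C)) at
efficiency 2. Reactions whose estimated per-cycle efficiency is not
strictly above the minimum (default 1.75) are discarded before
aggregation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from chloredit._stats import TTestResult, two_sample_t

logger = logging.getLogger(__name__)

DEFAULT_MIN_EFFICIENCY = 1.75
DEFAULT_N_BASELINE_CYCLES = 5
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AmplificationCurve:
    well_id: str
    cycles: np.ndarray  # 1..N
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        if len(self.cycles) != len(self.fluorescence):
            raise ValueError("cycles and fluorescence lengths differ")
        if len(self.cycles) < 15:
            raise ValueError("need at least 15 cycles")
        if not np.all(np.isfinite(self.fluorescence)):
            raise ValueError("fluorescence must be finite")


@dataclass(frozen=True)
class QpcrReaction:
    """One well with its called Ct and estimated efficiency."""

    well_id: str
    site: str
    allele: str
    treatment: str
    timepoint: str
    sample: str
    replicate: int
    curve: AmplificationCurve
    baseline: float | None = None
    ct: float | None = None
    efficiency: float | None = None
    passed_filter: bool = False


# ---------------------------------------------------------------------------
# Curve-level operations
# ---------------------------------------------------------------------------


def estimate_baseline(
    curve: AmplificationCurve, n_baseline_cycles: int = DEFAULT_N_BASELINE_CYCLES
) -> float:
    """Mean fluorescence over the first ``n_baseline_cycles`` cycles."""
    if n_baseline_cycles >= len(curve.cycles):
        raise ValueError("n_baseline_cycles must be < number of cycles")
    if n_baseline_cycles < 1:
        raise ValueError("n_baseline_cycles must be >= 1")
    return float(np.mean(curve.fluorescence[:n_baseline_cycles]))


def _default_threshold(
    curve: AmplificationCurve, baseline: float, n_baseline_cycles: int
) -> float:
    """baseline + 10*sd of the baseline cycles, floored at 2% of the signal
    range so noise-free (sd = 0) curves still get a usable threshold."""
    sd = float(np.std(curve.fluorescence[:n_baseline_cycles]))
    signal = float(np.max(curve.fluorescence) - baseline)
    return baseline + max(10.0 * sd, 0.02 * signal)


def call_ct(
    curve: AmplificationCurve,
    baseline: float | None = None,
    threshold: float | None = None,
    n_baseline_cycles: int = DEFAULT_N_BASELINE_CYCLES,
) -> float | None:
    """Fractional cycle of the first upward threshold crossing, or None.

    The crossing is interpolated between the two flanking cycles in log
    space (exact for an exponential segment), falling back to linear
    interpolation when the lower flank is non-positive. ``threshold`` is on
    the raw fluorescence scale.
    """
    if baseline is None:
        baseline = estimate_baseline(curve, n_baseline_cycles)
    if threshold is None:
        threshold = _default_threshold(curve, baseline, n_baseline_cycles)
    f = curve.fluorescence - baseline
    t = threshold - baseline
    if t <= 0:
        raise ValueError("threshold must exceed the baseline")
    above = f >= t
    idx = np.flatnonzero(above[1:] & ~above[:-1])
    if above[0]:
        return float(curve.cycles[0])
    if idx.size == 0:
        return None
    i = int(idx[0])  # crossing between cycles i and i+1
    f0, f1 = float(f[i]), float(f[i + 1])
    if f0 > 0 and f1 > f0:
        frac = (np.log(t) - np.log(f0)) / (np.log(f1) - np.log(f0))
    else:
        frac = (t - f0) / (f1 - f0)
    return float(curve.cycles[i] + frac * (curve.cycles[i + 1] - curve.cycles[i]))


def _best_loglinear_window(
    cycles: np.ndarray,
    f: np.ndarray,
    sd: float,
    window_sizes: tuple[int, ...],
    noise_frac: float,
    plateau_frac: float,
) -> tuple[float, float] | None:
    """Max-R^2 log-linear fit over candidate windows; returns (slope, intercept)."""
    plateau = float(np.max(f))
    if plateau <= 0:
        return None
    floor = max(5.0 * sd, noise_frac * plateau)
    ok = (f > floor) & (f < plateau_frac * plateau)
    n = len(f)
    logf = np.full(n, np.nan)
    pos = f > 0
    logf[pos] = np.log10(f[pos])
    best: tuple[float, float, float] | None = None  # (r2, slope, intercept)
    for w in window_sizes:
        for start in range(0, n - w + 1):
            sl = slice(start, start + w)
            if not np.all(ok[sl]):
                continue
            x = cycles[sl].astype(float)
            y = logf[sl]
            slope, intercept = np.polyfit(x, y, 1)
            resid = y - (slope * x + intercept)
            tot = np.sum((y - y.mean()) ** 2)
            r2 = 1.0 - np.sum(resid**2) / tot if tot > 0 else 0.0
            if best is None or r2 > best[0]:
                best = (r2, slope, intercept)
    if best is None:
        return None
    return best[1], best[2]


def estimate_efficiency(
    curve: AmplificationCurve,
    baseline: float | None = None,
    n_baseline_cycles: int = DEFAULT_N_BASELINE_CYCLES,
    window_sizes: tuple[int, ...] = (4, 5, 6),
    noise_frac: float = 1e-4,
    plateau_frac: float = 0.5,
) -> float | None:
    """Window-of-linearity estimate of the per-cycle amplification factor.

    Candidate points are baseline-subtracted fluorescence values above the
    noise floor (max of 5*baseline sd and ``noise_frac`` of the plateau)
    and below ``plateau_frac`` of the plateau. Over all windows of 4-6
    consecutive candidate cycles, fits log10(fluorescence) ~ cycle and
    takes the window maximizing R^2. The baseline is then refined once by
    subtracting the fitted exponential's contribution to the baseline
    cycles (the early cycles are not signal-free, and that contamination
    otherwise inflates the slope), and the scan is repeated. Returns
    10**slope; None when no window of >= 4 points exists.
    """
    if baseline is None:
        baseline = estimate_baseline(curve, n_baseline_cycles)
    sd = float(np.std(curve.fluorescence[:n_baseline_cycles]))
    raw_baseline_mean = float(np.mean(curve.fluorescence[:n_baseline_cycles]))
    fit = None
    for _ in range(2):
        f = curve.fluorescence - baseline
        fit = _best_loglinear_window(
            curve.cycles, f, sd, window_sizes, noise_frac, plateau_frac
        )
        if fit is None:
            return None
        slope, intercept = fit
        early = curve.cycles[:n_baseline_cycles].astype(float)
        contamination = float(np.mean(10.0 ** (intercept + slope * early)))
        if not np.isfinite(contamination) or contamination < 0:
            break
        refined = raw_baseline_mean - contamination
        if abs(refined - baseline) < 1e-12:
            break
        baseline = refined
    return float(10.0 ** fit[0])


# ---------------------------------------------------------------------------
# Reaction-level operations
# ---------------------------------------------------------------------------


def filter_reactions(
    reactions: Sequence[QpcrReaction],
    min_efficiency: float = DEFAULT_MIN_EFFICIENCY,
) -> list[QpcrReaction]:
    """Keep reactions with efficiency strictly above ``min_efficiency``.

    Reactions with no efficiency estimate are removed. Returns all
    reactions with ``passed_filter`` set; downstream aggregation uses only
    the passing ones.
    """
    out = []
    n_removed = 0
    for r in reactions:
        passed = r.efficiency is not None and r.efficiency > min_efficiency
        if not passed:
            n_removed += 1
        out.append(replace(r, passed_filter=passed))
    if n_removed:
        logger.info(
            "efficiency filter removed %d/%d reactions (min %.3g)",
            n_removed,
            len(reactions),
            min_efficiency,
        )
    return out


def editing_fraction_from_ct(
    ct_t: float | None,
    ct_c: float | None,
    eff_t: float = 2.0,
    eff_c: float = 2.0,
) -> float | None:
    """Q_T / (Q_T + Q_C) with Q = eff^(-ct); None if either Ct is uncalled."""
    if ct_t is None or ct_c is None:
        return None
    if eff_t <= 1.0 or eff_c <= 1.0:
        raise ValueError("efficiencies must be > 1")
    # work in logs to avoid underflow at large Ct
    log_qt = -ct_t * np.log(eff_t)
    log_qc = -ct_c * np.log(eff_c)
    m = max(log_qt, log_qc)
    qt, qc = np.exp(log_qt - m), np.exp(log_qc - m)
    return float(qt / (qt + qc))


def primer_efficiency_report(reactions: Sequence[QpcrReaction]) -> pd.DataFrame:
    """Mean estimated efficiency per primer (site x allele) and treatment."""
    rows = [
        {
            "site": r.site,
            "allele": r.allele,
            "treatment": r.treatment,
            "efficiency": r.efficiency,
        }
        for r in reactions
        if r.efficiency is not None
    ]
    if not rows:
        return pd.DataFrame(columns=["site", "allele", "treatment", "mean_efficiency", "n"])
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["site", "allele", "treatment"], sort=True)["efficiency"]
        .agg(mean_efficiency="mean", n="count")
        .reset_index()
    )
    return out


# ---------------------------------------------------------------------------
# Plate-level analysis
# ---------------------------------------------------------------------------


def load_plate(plate_csv: str | Path) -> dict[str, AmplificationCurve]:
    df = pd.read_csv(plate_csv)
    curves = {}
    for well, grp in df.groupby("well", sort=True):
        grp = grp.sort_values("cycle")
        curves[str(well)] = AmplificationCurve(
            well_id=str(well),
            cycles=grp["cycle"].to_numpy(),
            fluorescence=grp["fluorescence"].to_numpy(dtype=float),
        )
    return curves


def load_plate_map(map_csv: str | Path) -> pd.DataFrame:
    df = pd.read_csv(map_csv)
    required = {"well", "site", "allele", "treatment", "sample", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"plate map is missing columns: {sorted(missing)}")
    if "timepoint" not in df.columns:
        df["timepoint"] = "4h"
    return df


def build_reactions(
    curves: Mapping[str, AmplificationCurve],
    plate_map: pd.DataFrame,
    threshold: float | None = None,
    n_baseline_cycles: int = DEFAULT_N_BASELINE_CYCLES,
) -> list[QpcrReaction]:
    """Assemble reactions from curves + map and call baseline/Ct/efficiency.

    When no threshold is given, one common threshold is used for the whole
    plate (the median of the per-well defaults), mirroring instrument
    software: a per-well threshold would inject baseline-noise jitter
    straight into every Ct difference.
    """
    for _, row in plate_map.iterrows():
        if str(row["well"]) not in curves:
            raise KeyError(f"plate map well {row['well']} missing from plate data")
    if threshold is None and len(plate_map):
        defaults = []
        for well in plate_map["well"].astype(str).unique():
            curve = curves[well]
            b = estimate_baseline(curve, n_baseline_cycles)
            defaults.append(_default_threshold(curve, b, n_baseline_cycles))
        threshold = float(np.median(defaults))
    reactions = []
    for _, row in plate_map.iterrows():
        well = str(row["well"])
        curve = curves[well]
        baseline = estimate_baseline(curve, n_baseline_cycles)
        ct = call_ct(curve, baseline, threshold, n_baseline_cycles)
        eff = estimate_efficiency(curve, baseline, n_baseline_cycles)
        reactions.append(
            QpcrReaction(
                well_id=well,
                site=str(row["site"]),
                allele=str(row["allele"]),
                treatment=str(row["treatment"]),
                timepoint=str(row["timepoint"]),
                sample=str(row["sample"]),
                replicate=int(row["replicate"]),
                curve=curve,
                baseline=baseline,
                ct=ct,
                efficiency=eff,
            )
        )
    return reactions


def sample_fractions(
    reactions: Sequence[QpcrReaction],
    use_estimated_efficiency: bool = False,
    default_efficiency: float = 2.0,
) -> pd.DataFrame:
    """Per-sample edited fractions from filtered reactions.

    Technical replicates are aggregated by mean Ct per allele, then the
    fraction is computed once per (site, timepoint, sample). By default the
    nominal efficiency 2 is used for both alleles (the 2^-ddCt convention;
    estimated efficiencies serve the filter and the bias report, where the
    Ct lever arm cannot amplify their noise). Setting
    ``use_estimated_efficiency`` substitutes the mean estimated primer
    efficiency per (site, allele, treatment). Sample groups with no passing
    well for either allele are flagged unusable and skipped.
    """
    passed = [r for r in reactions if r.passed_filter and r.ct is not None]
    eff_by_primer: dict[tuple[str, str, str], float] = {}
    if use_estimated_efficiency:
        df_eff = primer_efficiency_report(passed)
        for _, row in df_eff.iterrows():
            eff_by_primer[(row["site"], row["allele"], row["treatment"])] = float(
                row["mean_efficiency"]
            )

    groups: dict[tuple[str, str, str, str], dict[str, list[float]]] = {}
    for r in passed:
        key = (r.site, r.timepoint, r.treatment, r.sample)
        groups.setdefault(key, {"C": [], "T": []})[r.allele].append(r.ct)

    rows = []
    for (site, tp, trt, sample), cts in sorted(groups.items()):
        if not cts["C"] or not cts["T"]:
            logger.warning(
                "sample %s at %s (%s) lacks a passing %s-allele reaction; skipped",
                sample,
                site,
                tp,
                "C" if not cts["C"] else "T",
            )
            continue
        eff_t = eff_by_primer.get((site, "T", trt), default_efficiency)
        eff_c = eff_by_primer.get((site, "C", trt), default_efficiency)
        frac = editing_fraction_from_ct(
            float(np.mean(cts["T"])), float(np.mean(cts["C"])), eff_t, eff_c
        )
        rows.append(
            {
                "site": site,
                "timepoint": tp,
                "treatment": trt,
                "sample": sample,
                "edited_fraction": frac,
                "n_wells_T": len(cts["T"]),
                "n_wells_C": len(cts["C"]),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "site",
            "timepoint",
            "treatment",
            "sample",
            "edited_fraction",
            "n_wells_T",
            "n_wells_C",
        ],
    )


def compare_treatment(
    fractions: pd.DataFrame,
    groups: tuple[str, str] = ("control", "salt"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Treatment comparison per (site, timepoint): means in percent + t-test p."""
    rows = []
    for (site, tp), grp in fractions.groupby(["site", "timepoint"], sort=True):
        a = grp.loc[grp["treatment"] == groups[0], "edited_fraction"].tolist()
        b = grp.loc[grp["treatment"] == groups[1], "edited_fraction"].tolist()
        res: TTestResult = two_sample_t(a, b)
        rows.append(
            {
                "site": site,
                "timepoint": tp,
                f"mean_{groups[0]}_pct": 100.0 * float(np.mean(a)) if a else float("nan"),
                f"mean_{groups[1]}_pct": 100.0 * float(np.mean(b)) if b else float("nan"),
                "p_value": float("nan") if res.p_value is None else res.p_value,
                "significant": res.p_value is not None and res.p_value < alpha,
                "degenerate": res.degenerate,
            }
        )
    return pd.DataFrame(rows)


def analyze_plate(
    plate_csv: str | Path,
    map_csv: str | Path,
    min_efficiency: float = DEFAULT_MIN_EFFICIENCY,
    threshold: float | None = None,
    use_estimated_efficiency: bool = False,
    alpha: float = 0.05,
) -> tuple[list[QpcrReaction], pd.DataFrame, pd.DataFrame]:
    """Full plate analysis: reactions -> filtered -> fractions -> comparison."""
    curves = load_plate(plate_csv)
    plate_map = load_plate_map(map_csv)
    reactions = build_reactions(curves, plate_map, threshold=threshold)
    reactions = filter_reactions(reactions, min_efficiency)
    fractions = sample_fractions(reactions, use_estimated_efficiency)
    comparison = compare_treatment(fractions, alpha=alpha)
    return reactions, fractions, comparison


# ---------------------------------------------------------------------------
# Primer design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PrimerSet:
    c_primer: str
    t_primer: str
    universal: str
    orientation: str  # orientation of the allele-specific primers
    discriminant: str  # 'three_prime' or 'five_prime'


def design_allele_primers(
    cds_sequence: str,
    cds_position: int,
    primer_length: int = 20,
    discriminant: str = "three_prime",
    orientation: str = "forward",
    gap: int = 5,
) -> PrimerSet:
    """Two allele-specific primers (differing only at the editing site) plus
    one universal primer on the opposite strand.

    ``discriminant`` places the discriminating base at the 3' terminus
    (standard allele-specific design) or at the 5' first position;
    ``orientation`` is the strand of the specific primers, with the
    universal primer on the other strand.
    """
    if discriminant not in ("three_prime", "five_prime"):
        raise ValueError("discriminant must be 'three_prime' or 'five_prime'")
    if orientation not in ("forward", "reverse"):
        raise ValueError("orientation must be 'forward' or 'reverse'")
    pos0 = cds_position - 1
    L, n = primer_length, len(cds_sequence)
    if not 0 <= pos0 < n:
        raise ValueError("cds_position outside the CDS")

    def cut(lo: int, hi: int) -> str:
        if lo < 0 or hi > n:
            raise ValueError(
                f"insufficient flank for a {L} nt primer at position {cds_position}"
            )
        return cds_sequence[lo:hi]

    if orientation == "forward":
        if discriminant == "three_prime":
            left = cut(pos0 - L + 1, pos0)
            c_p, t_p = left + "C", left + "T"
            universal = _revcomp(cut(pos0 + 1 + gap, pos0 + 1 + gap + L))
        else:
            right = cut(pos0 + 1, pos0 + L)
            c_p, t_p = "C" + right, "T" + right
            universal = _revcomp(cut(pos0 + L + gap, pos0 + L + gap + L))
    else:
        if discriminant == "three_prime":
            right = cut(pos0 + 1, pos0 + L)
            c_p, t_p = _revcomp("C" + right), _revcomp("T" + right)
            universal = cut(pos0 - gap - L, pos0 - gap)
        else:
            left = cut(pos0 - L + 1, pos0)
            c_p, t_p = _revcomp(left + "C"), _revcomp(left + "T")
            universal = cut(pos0 - L - gap - L + 1, pos0 - L - gap + 1)

    return PrimerSet(c_p, t_p, universal, orientation, discriminant)
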