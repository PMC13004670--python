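"""ELISA titer interpolation, ELISpot calls and seromics hit counting.

A reciprocal titer is the dilution at which the titration curve —
readout regressed on log10(reciprocal dilution) — meets the plate's
cutoff (negative-control mean + 3 SD by default); seropositivity is a
reciprocal titer above 100. ELISpot wells are positive above 50 spots
and at least twice background. Seromics arrays are quantile-normalized
within channel, z-scored against each array's negative-control spots
(median/MAD), and an antigen is a hit only when both duplicate spots
clear the threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

POSITIVITY_THRESHOLD = 100.0  # reciprocal titer must exceed this
DEFAULT_Z_THRESHOLD = 3.0
ELISPOT_MIN_SPOTS = 50.0
ELISPOT_FOLD = 2.0
ELISPOT_BACKGROUND_SANITY = 3.0
MIN_CONTROL_SPOTS = 10
_MAD_SCALE = 1.4826  # MAD -> SD under normality


# --------------------------------------------------------------------------
# ELISA
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TiterResult:
    sample: str
    antigen: str
    reciprocal_titer: float
    method: str  # interpolated | extrapolated_low | extrapolated_high | none
    positive: bool
    cutoff: float
    slope: float
    flag: str = ""


def cutoff_mean_plus_3sd(negative_control_readouts: Sequence[float]) -> float:
    """Default cutoff rule: negative-control mean + 3 SD, pooled."""
    neg = np.asarray(negative_control_readouts, dtype=float)
    if neg.size == 0:
        raise ValueError("cutoff rule needs negative-control readouts")
    sd = neg.std(ddof=1) if neg.size > 1 else 0.0
    return float(neg.mean() + 3.0 * sd)


def reciprocal_titer(
    dilutions: Sequence[float],
    readouts: Sequence[float],
    negative_control_readouts: Optional[Sequence[float]] = None,
    cutoff: Optional[float] = None,
    cutoff_rule: Callable[[Sequence[float]], float] = cutoff_mean_plus_3sd,
    sample: str = "",
    antigen: str = "",
) -> TiterResult:
    """Interpolated reciprocal titer for one titration curve.

    Fits ``readout ~ a + b * log10(reciprocal dilution)`` by least
    squares and solves for the cutoff crossing. Crossings outside
    ``[min dilution / 2, max dilution * 2]`` are clipped to the bound and
    labeled extrapolated; curves never reaching the cutoff (or with
    non-negative slope) yield titer 0 and method ``none``.
    """
    d = np.asarray(dilutions, dtype=float)
    y = np.asarray(readouts, dtype=float)
    if d.size < 2 or d.size != y.size:
        raise ValueError("need >= 2 (dilution, readout) points")
    if cutoff is None:
        if negative_control_readouts is None:
            raise ValueError("provide either cutoff or negative_control_readouts")
        cutoff = cutoff_rule(negative_control_readouts)

    b, a = np.polyfit(np.log10(d), y, 1)

    def result(titer, method, flag=""):
        return TiterResult(sample, antigen, float(titer), method,
                           bool(titer > POSITIVITY_THRESHOLD), float(cutoff),
                           float(b), flag)

    if np.all(y < cutoff):
        return result(0.0, "none")
    if b >= -1e-12:  # numerically flat counts as non-decreasing
        return result(0.0, "none", flag="nonnegative_slope")

    crossing = 10.0 ** ((cutoff - a) / b)
    lo, hi = d.min() / 2.0, d.max() * 2.0
    if crossing < lo:
        return result(lo, "extrapolated_low")
    if crossing > hi:
        return result(hi, "extrapolated_high")
    return result(crossing, "interpolated")


def titer_table(
    elisa: pd.DataFrame,
    cutoff_rule: Callable[[Sequence[float]], float] = cutoff_mean_plus_3sd,
) -> pd.DataFrame:
    """Apply :func:`reciprocal_titer` to a long-format ELISA plate table.

    Expects columns ``sample, antigen, dilution, readout`` and an
    ``is_negative_control`` 0/1 column; the negative-control pool is
    shared across the plate (pooled over dilutions).
    """
    neg = elisa[elisa["is_negative_control"].astype(bool)]
    if neg.empty:
        raise ValueError("plate table has no negative-control rows")
    cutoff = cutoff_rule(neg["readout"].to_numpy())
    rows = []
    test = elisa[~elisa["is_negative_control"].astype(bool)]
    if "is_positive_control" in test.columns:
        test = test[~test["is_positive_control"].astype(bool)]
    for (sample, antigen), grp in test.groupby(["sample", "antigen"], sort=True):
        grp = grp.sort_values("dilution")
        res = reciprocal_titer(
            grp["dilution"].to_numpy(), grp["readout"].to_numpy(),
            cutoff=cutoff, sample=str(sample), antigen=str(antigen),
        )
        rows.append(res.__dict__)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# ELISpot
# --------------------------------------------------------------------------

def elispot_positive(
    well_counts: Sequence[float],
    background_counts: Sequence[float],
    min_spots: float = ELISPOT_MIN_SPOTS,
    fold: float = ELISPOT_FOLD,
) -> Dict[str, object]:
    """Positivity call: mean count > *min_spots* AND >= *fold* x background.

    Raises when no background wells are supplied (the rule is undefined
    without a control); flags backgrounds above 3 spots per well.
    """
    test = np.asarray(well_counts, dtype=float)
    bg = np.asarray(background_counts, dtype=float)
    if bg.size == 0:
        raise ValueError("ELISpot rule undefined without background wells")
    if test.size == 0:
        raise ValueError("no test wells")
    mean_test = float(test.mean())
    mean_bg = float(bg.mean())
    return {
        "mean_test": mean_test,
        "mean_background": mean_bg,
        "positive": bool(mean_test > min_spots and mean_test >= fold * mean_bg),
        "background_flag": bool(mean_bg > ELISPOT_BACKGROUND_SANITY),
    }


def elispot_table(elispot: pd.DataFrame) -> pd.DataFrame:
    """Per-sample positivity from a long well table.

    Expects ``sample, condition, spot_count, is_background`` columns;
    background wells are pooled per sample.
    """
    rows = []
    for sample, grp in elispot.groupby("sample", sort=True):
        bg = grp[grp["is_background"].astype(bool)]["spot_count"].to_numpy()
        for condition, sub in grp[~grp["is_background"].astype(bool)].groupby(
            "condition", sort=True
        ):
            call = elispot_positive(sub["spot_count"].to_numpy(), bg)
            rows.append((sample, condition, call["mean_test"],
                         call["mean_background"], call["positive"],
                         call["background_flag"]))
    return pd.DataFrame(
        rows, columns=["sample", "condition", "mean_test", "mean_background",
                       "positive", "background_flag"],
    )


# --------------------------------------------------------------------------
# seromics
# --------------------------------------------------------------------------

def _quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Standard quantile normalization across columns (arrays)."""
    ranks = matrix.rank(method="average")
    sorted_vals = np.sort(matrix.to_numpy(), axis=0)
    mean_by_rank = sorted_vals.mean(axis=1)
    n = len(matrix)
    # interpolate for tied (fractional) ranks
    grid = np.arange(1, n + 1, dtype=float)
    out = {
        col: np.interp(ranks[col].to_numpy(), grid, mean_by_rank)
        for col in matrix.columns
    }
    return pd.DataFrame(out, index=matrix.index)


def seromics_hits(
    spots: pd.DataFrame,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
) -> pd.DataFrame:
    """Hit calling on a long seromics spot table.

    Expects ``sample, channel, antigen, antigen_class, is_control, spot,
    intensity``. Per array, every spot is z-scored against the array's
    negative-control spot distribution (median / scaled MAD) on the raw
    intensities — the per-array robust z is scale-free, and mapping tail
    ranks onto a cross-array reference would manufacture hits on arrays
    that have none. An antigen is a hit iff BOTH duplicate spots reach
    *z_threshold*. For cross-array comparability the reported
    ``normalized_signal`` is the duplicate median after quantile
    normalization of arrays within channel.
    """
    required = {"sample", "channel", "antigen", "antigen_class",
                "is_control", "spot", "intensity"}
    missing = required - set(spots.columns)
    if missing:
        raise ValueError(f"seromics table missing columns: {sorted(missing)}")

    out_rows = []
    for channel, chan_df in spots.groupby("channel", sort=True):
        wide = chan_df.pivot_table(
            index=["antigen", "antigen_class", "is_control", "spot"],
            columns="sample", values="intensity", sort=True,
        )
        norm = _quantile_normalize(wide)
        for sample in wide.columns:
            raw = wide[sample].reset_index().rename(columns={sample: "intensity"})
            raw["normalized"] = norm[sample].to_numpy()
            ctrl = raw[raw["is_control"].astype(bool)]
            if len(ctrl) < MIN_CONTROL_SPOTS:
                raise ValueError(
                    f"array ({sample}, {channel}) has {len(ctrl)} negative-control "
                    f"spots; need >= {MIN_CONTROL_SPOTS}"
                )
            med = float(ctrl["intensity"].median())
            mad = float(stats.median_abs_deviation(ctrl["intensity"])) * _MAD_SCALE
            if mad <= 0:
                mad = max(float(ctrl["intensity"].std(ddof=1)), 1e-12)
            raw["z"] = (raw["intensity"] - med) / mad
            tests = raw[~raw["is_control"].astype(bool)]
            for (antigen, cls), dup in tests.groupby(
                ["antigen", "antigen_class"], sort=True
            ):
                z = dup["z"].to_numpy()
                out_rows.append(
                    (sample, channel, antigen, cls,
                     float(dup["normalized"].median()), float(np.median(z)),
                     bool(np.all(z >= z_threshold)))
                )
    return pd.DataFrame(
        out_rows, columns=["sample", "channel", "antigen", "antigen_class",
                           "normalized_signal", "z_score", "hit"],
    )


def hit_class_summary(
    hits: pd.DataFrame,
    sample_annotation: pd.DataFrame,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Per-patient per-class hit counts plus responder-vs-NR rank tests.

    *sample_annotation* maps ``sample`` to ``patient, timepoint,
    response``. Returns ``(counts table, group-test table)``; deltas are
    post minus pre per patient, NaN when a timepoint is missing.
    """
    merged = hits.merge(sample_annotation, on="sample", how="left")
    counts = (
        merged.groupby(
            ["patient", "response", "timepoint", "channel", "antigen_class"],
            sort=True,
        )["hit"]
        .sum()
        .astype(int)
        .rename("n_hits")
        .reset_index()
    )

    # pre/post delta per patient/channel/class
    pivot = counts.pivot_table(
        index=["patient", "response", "channel", "antigen_class"],
        columns="timepoint", values="n_hits", sort=True,
    ).reset_index()
    if "post" in pivot.columns and "pre" in pivot.columns:
        pivot["delta_post_pre"] = pivot["post"] - pivot["pre"]
    else:
        pivot["delta_post_pre"] = np.nan
    counts = counts.merge(
        pivot[["patient", "channel", "antigen_class", "delta_post_pre"]],
        on=["patient", "channel", "antigen_class"], how="left",
    )

    test_rows = []
    per_patient = (
        counts.groupby(["patient", "response", "channel", "antigen_class"],
                       sort=True)["n_hits"].sum().reset_index()
    )
    for (channel, cls), grp in per_patient.groupby(["channel", "antigen_class"],
                                                   sort=True):
        r = grp[grp["response"] == "R"]["n_hits"].to_numpy()
        nr = grp[grp["response"] == "NR"]["n_hits"].to_numpy()
        if r.size and nr.size:
            if np.ptp(np.concatenate([r, nr])) == 0:
                p = 1.0  # identical constant counts carry no signal
            else:
                p = float(stats.mannwhitneyu(r, nr, alternative="two-sided").pvalue)
        else:
            p = np.nan
        test_rows.append((channel, cls, r.size, nr.size,
                          float(r.mean()) if r.size else np.nan,
                          float(nr.mean()) if nr.size else np.nan, p))
    tests = pd.DataFrame(
        test_rows, columns=["channel", "antigen_class", "n_R", "n_NR",
                            "mean_hits_R", "mean_hits_NR", "p_value"],
    )
    return counts, tests
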