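"""Synthetic ELISA titrations, ELISpot counts and seromics arrays.

ELISA readouts are linear in log10(reciprocal dilution) and cross the
configured cutoff exactly at the true titer before noise, so noiseless
titer recovery downstream must be exact.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .._constants import ANTIGEN_CLASSES
from .specs import SerologySpec, _spawn_rng

NEGATIVE_CONTROL_SAMPLE = "NEG_POOL"
POSITIVE_CONTROL_SAMPLE = "POS_POOL"


def antigen_panel(spec: SerologySpec) -> pd.DataFrame:
    """Antigen id / class table implied by ``n_antigens_by_class``."""
    rows = []
    for cls in ANTIGEN_CLASSES:
        for i in range(spec.n_antigens_by_class.get(cls, 0)):
            rows.append((f"{cls}_{i + 1:03d}", cls))
    return pd.DataFrame(rows, columns=["antigen", "antigen_class"])


def _elisa(spec: SerologySpec, rng: np.random.Generator) -> pd.DataFrame:
    dil = np.asarray(spec.dilutions, dtype=float)
    logd = np.log10(dil)
    rows: List[tuple] = []

    def noise() -> float:
        return float(rng.normal(0.0, spec.readout_noise_sd)) if spec.readout_noise_sd else 0.0

    for (sample, antigen), titer in spec.true_titers.items():
        warn = int(spec.titer_extrapolates(titer))
        for d, ld in zip(dil, logd):
            if titer is None:
                readout = 0.4 * spec.cutoff_readout + noise()
            else:
                # crosses cutoff_readout exactly at the true titer
                readout = spec.cutoff_readout + spec.curve_slope * (
                    ld - np.log10(titer)
                ) + noise()
            rows.append((sample, antigen, d, readout, 0, 0, warn))

    antigens = sorted({a for _, a in spec.true_titers})
    for antigen in antigens:
        for d in dil:
            # negative pool constructed so mean + 3*SD sits at the cutoff
            rows.append((NEGATIVE_CONTROL_SAMPLE, antigen, d,
                         spec.cutoff_readout - 3.0 * spec.readout_noise_sd + noise(),
                         1, 0, 0))
            rows.append((POSITIVE_CONTROL_SAMPLE, antigen, d,
                         4.0 * spec.cutoff_readout + noise(), 0, 1, 0))

    return pd.DataFrame(
        rows,
        columns=["sample", "antigen", "dilution", "readout",
                 "is_negative_control", "is_positive_control",
                 "extrapolation_warning"],
    )


def _elispot(spec: SerologySpec, rng: np.random.Generator) -> pd.DataFrame:
    reactive = {s for (s, _a), t in spec.true_titers.items() if t is not None}
    rows = []
    for sample in spec.elispot_samples:
        mean = (spec.elispot_reactive_mean if sample in reactive
                else spec.elispot_nonreactive_mean)
        for well in range(spec.elispot_wells_per_condition):
            rows.append((sample, "antigen_pulsed", well + 1,
                         int(rng.poisson(mean)), 0))
            rows.append((sample, "DMSO", well + 1,
                         int(rng.poisson(spec.elispot_background_mean)), 1))
    return pd.DataFrame(
        rows, columns=["sample", "condition", "well", "spot_count", "is_background"]
    )


def _seromics(spec: SerologySpec, rng: np.random.Generator) -> pd.DataFrame:
    samples = list(spec.seromics_samples) or sorted({s for s, _ in spec.true_titers})
    panel = antigen_panel(spec)
    antigens = list(zip(panel["antigen"], panel["antigen_class"])) + [
        (f"control_{i + 1:03d}", "control") for i in range(spec.seromics_n_controls)
    ]
    baseline = {a: float(rng.lognormal(np.log(500.0), spec.seromics_baseline_sigma))
                for a, _ in antigens}

    by_class: Dict[str, List[str]] = {}
    for a, cls in antigens:
        by_class.setdefault(cls, []).append(a)

    rows = []
    for sample in samples:
        for channel in ("IgG", "IgA"):
            hit_set = set()
            for cls, n in spec.seromics_hits.get((sample, channel), {}).items():
                hit_set.update(by_class.get(cls, [])[:n])
            array_factor = float(rng.lognormal(0.0, 0.1))
            for antigen, cls in antigens:
                fold = spec.seromics_hit_fold if antigen in hit_set else 1.0
                for spot in (1, 2):
                    intensity = (
                        baseline[antigen] * array_factor * fold
                        * float(np.exp(rng.normal(0.0, spec.seromics_noise_sd)))
                    )
                    rows.append((sample, channel, antigen, cls,
                                 int(cls == "control"), spot, intensity))
    return pd.DataFrame(
        rows,
        columns=["sample", "channel", "antigen", "antigen_class",
                 "is_control", "spot", "intensity"],
    )


def gen_serology(
    spec: SerologySpec,
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (ELISA plate table, ELISpot well table, seromics spot table)."""
    spec.validate()
    rng = _spawn_rng(spec.seed, "serology")
    elisa = _elisa(spec, rng)
    elispot = _elispot(spec, rng)
    seromics = _seromics(spec, rng)
    return elisa, elispot, seromics
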