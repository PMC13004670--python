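"""Validated parameter blocks for the synthetic generators."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Tuple

from .._constants import ANTIGEN_CLASSES, CLUSTERS, SPATIAL_MARKERS

_PROB_TOL = 1e-9


class SpecValidationError(ValueError):
    """Raised when a generator spec violates an invariant; names the field."""

    def __init__(self, spec_field: str, message: str):
        self.spec_field = spec_field
        super().__init__(f"{spec_field}: {message}")


def _default_cluster_props() -> dict:
    return {
        "naive B": 0.18,
        "memory B": 0.20,
        "activated B": 0.10,
        "switched B": 0.12,
        "unswitched B": 0.08,
        "atypical B": 0.07,
        "plasmablast": 0.08,
        "PC1": 0.07,
        "PC2": 0.06,
        "PC3": 0.04,
    }


# Isotype mixtures per compartment; B cells skew IgM/IgD/IgA, plasma
# compartments carry more class-switched IgG. Stand-in values.
B_CELL_ISOTYPE_PROBS = {
    "IGHM": 0.35, "IGHD": 0.15, "IGHG1": 0.08, "IGHG2": 0.05, "IGHG3": 0.03,
    "IGHG4": 0.02, "IGHA1": 0.20, "IGHA2": 0.10, "IGHE": 0.02,
}
PC_ISOTYPE_PROBS = {
    "IGHM": 0.15, "IGHD": 0.02, "IGHG1": 0.30, "IGHG2": 0.15, "IGHG3": 0.05,
    "IGHG4": 0.03, "IGHA1": 0.18, "IGHA2": 0.10, "IGHE": 0.02,
}


@dataclass(frozen=True)
class CohortSpec:
    """Parameters for the annotated-cohort + BCR repertoire generator."""

    n_patients_R: int = 4
    n_patients_NR: int = 6
    cells_per_sample: int = 200
    tissues: Tuple[str, ...] = ("tumor", "adjacent", "lymph_node")
    cluster_baseline_props: Mapping[str, float] = field(
        default_factory=_default_cluster_props
    )
    igg1_pc_logfc_R: float = 1.5
    dirichlet_precision: float = 60.0
    clone_size_distribution: float = 2.5  # power-law exponent, > 1
    shared_clone_fraction: float = 0.15
    bcr_coverage: float = 0.8  # fraction of cells with a c_call on the BCR row
    seed: int = 0

    def validate(self) -> "CohortSpec":
        for name in ("n_patients_R", "n_patients_NR", "cells_per_sample"):
            if int(getattr(self, name)) <= 0:
                raise SpecValidationError(name, "must be a positive count")
        if set(self.cluster_baseline_props) != set(CLUSTERS):
            raise SpecValidationError(
                "cluster_baseline_props", f"must cover exactly the clusters {CLUSTERS}"
            )
        total = sum(self.cluster_baseline_props.values())
        if abs(total - 1.0) > _PROB_TOL:
            raise SpecValidationError(
                "cluster_baseline_props", f"must sum to 1 (got {total!r})"
            )
        if any(p < 0 for p in self.cluster_baseline_props.values()):
            raise SpecValidationError("cluster_baseline_props", "negative probability")
        if self.dirichlet_precision <= 0:
            raise SpecValidationError("dirichlet_precision", "must be > 0")
        if self.clone_size_distribution <= 1:
            raise SpecValidationError("clone_size_distribution", "exponent must be > 1")
        if not 0.0 <= self.shared_clone_fraction <= 1.0:
            raise SpecValidationError("shared_clone_fraction", "must be in [0, 1]")
        if not 0.0 <= self.bcr_coverage <= 1.0:
            raise SpecValidationError("bcr_coverage", "must be in [0, 1]")
        if not self.tissues:
            raise SpecValidationError("tissues", "must be non-empty")
        return self


def _default_marker_probs_in() -> dict:
    return {"CD3": 0.45, "CD8": 0.30, "CD20": 0.55, "CD68": 0.10,
            "FOXP3": 0.05, "MZB1": 0.25}


def _default_marker_probs_bg() -> dict:
    return {"CD3": 0.05, "CD8": 0.03, "CD20": 0.02, "CD68": 0.10,
            "FOXP3": 0.02, "MZB1": 0.05}


@dataclass(frozen=True)
class SpatialSpec:
    """Parameters for the synthetic mIHC centroid field."""

    field_width_um: float = 1000.0
    field_height_um: float = 1000.0
    n_aggregates: int = 4
    aggregate_radius_um: float = 40.0
    cells_per_aggregate: int = 60
    background_density: float = 2e-4  # cells per µm²
    marker_probs_in_aggregate: Mapping[str, float] = field(
        default_factory=_default_marker_probs_in
    )
    marker_probs_background: Mapping[str, float] = field(
        default_factory=_default_marker_probs_bg
    )
    min_aggregate_gap_um: float = 50.0
    seed: int = 0

    def validate(self) -> "SpatialSpec":
        if self.field_width_um <= 0 or self.field_height_um <= 0:
            raise SpecValidationError("field_width_um", "field dimensions must be > 0")
        if self.n_aggregates < 0:
            raise SpecValidationError("n_aggregates", "must be >= 0")
        if self.aggregate_radius_um <= 0:
            raise SpecValidationError("aggregate_radius_um", "must be > 0")
        if self.cells_per_aggregate <= 0:
            raise SpecValidationError("cells_per_aggregate", "must be > 0")
        if self.background_density < 0:
            raise SpecValidationError("background_density", "must be >= 0")
        # the 10-µm linkage rule must not be able to bridge two aggregates
        if self.min_aggregate_gap_um <= 10.0:
            raise SpecValidationError(
                "min_aggregate_gap_um", "must exceed the 10 µm linkage distance"
            )
        for name in ("marker_probs_in_aggregate", "marker_probs_background"):
            probs = getattr(self, name)
            if set(probs) != set(SPATIAL_MARKERS):
                raise SpecValidationError(name, f"must cover markers {SPATIAL_MARKERS}")
            if any(not 0.0 <= p <= 1.0 for p in probs.values()):
                raise SpecValidationError(name, "probabilities must be in [0, 1]")
        return self


def _default_antigen_counts() -> dict:
    return {"CTA": 8, "tumor_associated": 8, "other": 4}


@dataclass(frozen=True)
class SerologySpec:
    """Parameters for ELISA / ELISpot / seromics generation.

    ``true_titers`` maps ``(sample, antigen)`` to a reciprocal titer, or to
    ``None`` for a seronegative curve. Titration curves are linear in
    log10(reciprocal dilution) with slope ``curve_slope`` and cross
    ``cutoff_readout`` exactly at the true titer before noise.
    """

    dilutions: Tuple[float, ...] = (100.0, 400.0, 1600.0, 6400.0)
    true_titers: Mapping[Tuple[str, str], Optional[float]] = field(default_factory=dict)
    readout_noise_sd: float = 0.0
    cutoff_readout: float = 10.0
    curve_slope: float = -6.0
    n_antigens_by_class: Mapping[str, int] = field(default_factory=_default_antigen_counts)
    # ELISpot: mean spot counts for reactive wells, non-reactive wells and
    # background (non-pulsed) wells; conditions listed per sample.
    elispot_samples: Tuple[str, ...] = ()
    elispot_reactive_mean: float = 120.0
    elispot_nonreactive_mean: float = 15.0
    elispot_background_mean: float = 1.0
    elispot_wells_per_condition: int = 3
    # seromics: hits per (sample, channel) per antigen class; samples default
    # to the ELISA samples when left empty.
    seromics_samples: Tuple[str, ...] = ()
    seromics_hits: Mapping[Tuple[str, str], Mapping[str, int]] = field(default_factory=dict)
    seromics_n_controls: int = 16
    seromics_hit_fold: float = 8.0
    seromics_baseline_sigma: float = 0.3  # lognormal sigma of per-antigen baselines
    seromics_noise_sd: float = 0.08  # lognormal sigma on spot intensities
    seed: int = 0

    def validate(self) -> "SerologySpec":
        dil = tuple(self.dilutions)
        if len(dil) < 2 or any(b <= a for a, b in zip(dil, dil[1:])):
            raise SpecValidationError("dilutions", "must be strictly increasing, len >= 2")
        if self.readout_noise_sd < 0:
            raise SpecValidationError("readout_noise_sd", "must be >= 0")
        if self.cutoff_readout <= 0:
            raise SpecValidationError("cutoff_readout", "must be > 0")
        if self.curve_slope >= 0:
            raise SpecValidationError("curve_slope", "must be negative")
        if set(self.n_antigens_by_class) - set(ANTIGEN_CLASSES):
            raise SpecValidationError(
                "n_antigens_by_class", f"classes must be among {ANTIGEN_CLASSES}"
            )
        if any(n < 0 for n in self.n_antigens_by_class.values()):
            raise SpecValidationError("n_antigens_by_class", "counts must be >= 0")
        for (sample, antigen), titer in self.true_titers.items():
            if titer is not None and titer <= 0:
                raise SpecValidationError(
                    "true_titers", f"({sample}, {antigen}): titer must be > 0 or None"
                )
        if self.seromics_n_controls < 10:
            raise SpecValidationError("seromics_n_controls", "need >= 10 control spots")
        return self

    def titer_extrapolates(self, titer: Optional[float]) -> bool:
        """True when a true titer lies outside the trusted titration window."""
        if titer is None:
            return False
        lo = min(self.dilutions) / 4.0
        hi = max(self.dilutions) * 4.0
        return not (lo < titer < hi)


def _spawn_rng(seed: int, label: str):
    """Deterministic child RNG derived from (seed, label)."""
    import hashlib

    import numpy as np

    digest = hashlib.sha256(f"{seed}:{label}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "little"))
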