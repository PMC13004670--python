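"""Synthetic annotated cohort with a matched BCR repertoire.

Per sample, cluster×isotype cell counts are Dirichlet-multinomial around a
baseline composition; responder tumor samples have the IgG1 plasma-cell
mean multiplied by ``2**igg1_pc_logfc_R`` before renormalization.
Clonotypes get heavy-tailed (truncated power-law) sizes, and a configurable
fraction of multi-cell clones spans two compartments of the same patient.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .._constants import CLUSTERS, ISOTYPES, PC_CLUSTERS, TIMEPOINTS
from .specs import B_CELL_ISOTYPE_PROBS, PC_ISOTYPE_PROBS, CohortSpec, _spawn_rng

_V_GENES = tuple(f"IGHV{f}-{n}*01" for f, n in
                 [(1, 2), (1, 69), (3, 7), (3, 23), (3, 30), (4, 34), (4, 39), (5, 51)])
_J_GENES = tuple(f"IGHJ{i}*01" for i in range(1, 7))

_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = tuple(c for c in _CODONS if c not in _STOPS)

_CODON_AA = {}
for _codon, _aa in zip(
    _CODONS,
    # standard genetic code, TCAG order flattened to ACGT lexicographic below
    "KNKNTTTTRSRSIIMIQHQHPPPPRRRRLLLLEDEDAAAAGGGGVVVV*Y*YSSSS*CWCLFLF",
):
    _CODON_AA[_codon] = _aa


def _translate(nt: str) -> str:
    return "".join(_CODON_AA[nt[i:i + 3]] for i in range(0, len(nt), 3))


def _random_junction(rng: np.random.Generator) -> Tuple[str, str]:
    """Random in-frame junction: Cys...Trp, 36–60 nt, no stop codons."""
    n_codons = int(rng.integers(12, 21))  # 36..60 nt
    middle = rng.choice(len(_SENSE_CODONS), size=n_codons - 2)
    nt = "TGT" + "".join(_SENSE_CODONS[i] for i in middle) + "TGG"
    return nt, _translate(nt)


def _category_means(spec: CohortSpec, responder_tumor: bool) -> np.ndarray:
    """Mean proportion per (cluster, isotype) category, optionally shifted."""
    means = np.empty(len(CLUSTERS) * len(ISOTYPES))
    idx = 0
    for cluster in CLUSTERS:
        iso_probs = PC_ISOTYPE_PROBS if cluster in PC_CLUSTERS else B_CELL_ISOTYPE_PROBS
        for iso in ISOTYPES:
            m = spec.cluster_baseline_props[cluster] * iso_probs[iso]
            if responder_tumor and cluster in PC_CLUSTERS and iso == "IGHG1":
                m *= 2.0 ** spec.igg1_pc_logfc_R
            means[idx] = m
            idx += 1
    return means / means.sum()


def _clone_size_pmf(exponent: float, max_size: int) -> np.ndarray:
    k = np.arange(1, max_size + 1, dtype=float)
    pmf = k ** (-exponent)
    return pmf / pmf.sum()


def _assign_clones(
    rng: np.random.Generator,
    cells_by_comp: Dict[Tuple[str, str], List[str]],
    spec: CohortSpec,
) -> List[dict]:
    """Partition one patient's cells into clones with power-law sizes."""
    pools = {comp: list(cells) for comp, cells in cells_by_comp.items() if cells}
    for comp in pools:
        rng.shuffle(pools[comp])
    pmf = _clone_size_pmf(spec.clone_size_distribution, spec.cells_per_sample)
    sizes = np.arange(1, spec.cells_per_sample + 1)
    clones: List[dict] = []
    comp_order = sorted(pools)
    while any(pools.values()):
        s = int(rng.choice(sizes, p=pmf))
        nonempty = [c for c in comp_order if pools[c]]
        shared = (
            s >= 2
            and len(nonempty) >= 2
            and rng.random() < spec.shared_clone_fraction
        )
        members: List[str] = []
        if shared:
            picked = [nonempty[i] for i in rng.choice(len(nonempty), size=2, replace=False)]
            # at least one member per chosen compartment
            quota = {picked[0]: 1, picked[1]: 1}
            for _ in range(s - 2):
                quota[picked[int(rng.integers(2))]] += 1
            for comp in picked:
                take = min(quota[comp], len(pools[comp]))
                members.extend(pools[comp][:take])
                del pools[comp][:take]
        else:
            comp = nonempty[int(rng.integers(len(nonempty)))]
            take = min(s, len(pools[comp]))
            members.extend(pools[comp][:take])
            del pools[comp][:take]
        if members:
            clones.append({"members": members})
    return clones


def gen_cohort_repertoire(
    spec: CohortSpec,
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict]:
    """Generate (annotation, AIRR rearrangements, IGHC UMI counts, registry).

    The registry records the ground-truth isotype of every cell and the
    exact clone partition (members, compartments), sufficient to score
    isotype rescue, expansion calls and shared-clone tracking exactly.
    """
    spec.validate()
    rng = _spawn_rng(spec.seed, "cohort")

    patients = [f"R{i + 1:02d}" for i in range(spec.n_patients_R)] + [
        f"N{i + 1:02d}" for i in range(spec.n_patients_NR)
    ]
    responses = {p: ("R" if p.startswith("R") else "NR") for p in patients}

    categories = [(cl, iso) for cl in CLUSTERS for iso in ISOTYPES]
    ann_rows = []
    cell_isotype: Dict[str, str] = {}
    cells_by_patient_comp: Dict[str, Dict[Tuple[str, str], List[str]]] = {
        p: {} for p in patients
    }

    for patient in patients:
        for tissue in spec.tissues:
            for timepoint in TIMEPOINTS:
                sample = f"{patient}_{tissue}_{timepoint}"
                means = _category_means(
                    spec, responses[patient] == "R" and tissue == "tumor"
                )
                p = rng.dirichlet(spec.dirichlet_precision * means)
                counts = rng.multinomial(spec.cells_per_sample, p)
                i_cell = 0
                comp = (tissue, timepoint)
                comp_cells = cells_by_patient_comp[patient].setdefault(comp, [])
                for (cluster, iso), n in zip(categories, counts):
                    for _ in range(int(n)):
                        cell_id = f"{sample}_c{i_cell:05d}"
                        i_cell += 1
                        ann_rows.append(
                            (cell_id, patient, sample, tissue, timepoint,
                             cluster, responses[patient])
                        )
                        cell_isotype[cell_id] = iso
                        comp_cells.append(cell_id)

    annotation = pd.DataFrame(
        ann_rows,
        columns=["cell_id", "patient", "sample", "tissue", "timepoint",
                 "cluster", "response"],
    )

    # ---- clones -----------------------------------------------------------
    comp_of_cell = dict(
        zip(annotation["cell_id"], zip(annotation["tissue"], annotation["timepoint"]))
    )
    registry_clones = []
    seen_junctions = set()
    airr_rows = []
    for patient in patients:
        clones = _assign_clones(rng, cells_by_patient_comp[patient], spec)
        for clone in clones:
            while True:
                junction, junction_aa = _random_junction(rng)
                if junction not in seen_junctions:
                    seen_junctions.add(junction)
                    break
            v_call = _V_GENES[int(rng.integers(len(_V_GENES)))]
            j_call = _J_GENES[int(rng.integers(len(_J_GENES)))]
            comps = sorted({comp_of_cell[c] for c in clone["members"]})
            registry_clones.append(
                {
                    "patient": patient,
                    "junction": junction,
                    "junction_aa": junction_aa,
                    "members": sorted(clone["members"]),
                    "compartments": [list(c) for c in comps],
                    "size": len(clone["members"]),
                }
            )
            for cell_id in clone["members"]:
                has_c_call = rng.random() < spec.bcr_coverage
                airr_rows.append(
                    (cell_id, "IGH", v_call, j_call,
                     cell_isotype[cell_id] if has_c_call else "",
                     junction, junction_aa, "T")
                )

    airr = pd.DataFrame(
        airr_rows,
        columns=["cell_id", "locus", "v_call", "j_call", "c_call",
                 "junction", "junction_aa", "productive"],
    ).sort_values("cell_id", kind="stable", ignore_index=True)

    # ---- IGHC UMIs --------------------------------------------------------
    # dominant isotype: Negative-Binomial(mean 8, dispersion 2) via
    # gamma-Poisson mixture; all other constant genes: Poisson(0.2).
    cell_ids = annotation["cell_id"].to_numpy()
    n_cells = len(cell_ids)
    umis = rng.poisson(0.2, size=(n_cells, len(ISOTYPES)))
    dom_idx = np.array([ISOTYPES.index(cell_isotype[c]) for c in cell_ids])
    lam = rng.gamma(shape=2.0, scale=8.0 / 2.0, size=n_cells)
    umis[np.arange(n_cells), dom_idx] = rng.poisson(lam)
    ighc = pd.DataFrame(umis, columns=list(ISOTYPES))
    ighc.insert(0, "cell_id", cell_ids)

    registry = {
        "clones": registry_clones,
        "cell_isotype": cell_isotype,
        "params": {
            "igg1_pc_logfc_R": spec.igg1_pc_logfc_R,
            "shared_clone_fraction": spec.shared_clone_fraction,
            "bcr_coverage": spec.bcr_coverage,
            "seed": spec.seed,
        },
    }
    return annotation, airr, ighc, registry
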