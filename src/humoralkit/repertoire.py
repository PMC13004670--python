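"""BCR isotype assignment, clonotyping, expansion and clone tracking.

Isotypes come from the rearrangement ``c_call`` when present and are
otherwise rescued from IGH constant-region UMI counts (argmax gene,
subject to minimum-count and dominance thresholds). Clonotypes are keyed
on the heavy-chain junction within patient — amino acid by default, with
nucleotide and V+J+aa key modes available — and a clone is "expanded"
when it holds two or more cells.
"""

from __future__ import annotations

import hashlib
import logging
import re
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._constants import ISOTYPES

logger = logging.getLogger(__name__)

KEY_MODES = ("junction_aa", "junction_nt", "vj_junction_aa")
_NT_RE = re.compile(r"^[ACGT]+$")

DEFAULT_RESCUE_MIN_UMIS = 3
DEFAULT_RESCUE_MIN_FRACTION = 0.6


# --------------------------------------------------------------------------
# isotype assignment
# --------------------------------------------------------------------------

def _productive_mask(airr: pd.DataFrame) -> pd.Series:
    prod = airr.get("productive")
    if prod is None:
        return pd.Series(True, index=airr.index)
    return prod.astype(str).str.upper().isin({"T", "TRUE", "1"})


def _pick_igh_row(group: pd.DataFrame) -> pd.Series:
    """One productive IGH row per cell; ties broken by highest UMI count."""
    if len(group) == 1:
        return group.iloc[0]
    if "duplicate_count" in group.columns:
        group = group.sort_values("duplicate_count", ascending=False, kind="stable")
    return group.iloc[0]


def _isotype_from_c_call(c_call: str) -> Optional[str]:
    for iso in ISOTYPES:
        if c_call.upper().startswith(iso):
            return iso
    return None


def assign_isotypes(
    airr: pd.DataFrame,
    ighc_umis: pd.DataFrame,
    rescue_min_umis: int = DEFAULT_RESCUE_MIN_UMIS,
    rescue_min_fraction: float = DEFAULT_RESCUE_MIN_FRACTION,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell isotype calls plus a BCR×expression concordance matrix.

    Cells with a usable ``c_call`` on their (single, productive, IGH)
    rearrangement get ``source="bcr"``. Cells without one get the argmax
    IGHC gene iff its UMIs >= *rescue_min_umis* and its share of total
    IGHC UMIs >= *rescue_min_fraction*; otherwise ``"ambiguous"``. The
    concordance matrix cross-tabulates BCR calls against the expression
    rule for cells where both are available.
    """
    umi_cols = [c for c in ISOTYPES if c in ighc_umis.columns]
    umi_lookup = (
        ighc_umis.set_index("cell_id")[umi_cols] if len(ighc_umis) else pd.DataFrame()
    )

    bcr_call: dict = {}
    multi_chain_flag: dict = {}
    if len(airr):
        igh = airr[(airr["locus"] == "IGH") & _productive_mask(airr)]
        for cell_id, group in igh.groupby("cell_id", sort=True):
            if len(group) > 1:
                multi_chain_flag[cell_id] = True
                logger.warning("cell %s has %d productive IGH chains; keeping one",
                               cell_id, len(group))
            row = _pick_igh_row(group)
            c_call = str(row.get("c_call", "") or "")
            bcr_call[cell_id] = _isotype_from_c_call(c_call) if c_call.strip() else None

    def expression_call(cell_id) -> Tuple[str, float]:
        """(isotype or 'ambiguous', dominant fraction) from IGHC UMIs."""
        if cell_id not in umi_lookup.index:
            return "ambiguous", np.nan
        counts = umi_lookup.loc[cell_id].to_numpy(dtype=float)
        total = counts.sum()
        if total <= 0:
            return "ambiguous", np.nan
        top = counts.max()
        frac = top / total
        # a tie for the argmax is ambiguous regardless of thresholds
        if (counts == top).sum() > 1:
            return "ambiguous", frac
        if top < rescue_min_umis or frac < rescue_min_fraction:
            return "ambiguous", frac
        return umi_cols[int(np.argmax(counts))], frac

    cells = sorted(set(bcr_call) | (set(umi_lookup.index) if len(umi_lookup) else set()))
    rows = []
    concordance_pairs = []
    for cell_id in cells:
        iso_bcr = bcr_call.get(cell_id)
        if iso_bcr is not None:
            rows.append((cell_id, iso_bcr, "bcr", np.nan,
                         bool(multi_chain_flag.get(cell_id, False))))
            expr_iso, _ = expression_call(cell_id)
            concordance_pairs.append((iso_bcr, expr_iso))
        else:
            expr_iso, frac = expression_call(cell_id)
            rows.append((cell_id, expr_iso, "expression_rescue", frac,
                         bool(multi_chain_flag.get(cell_id, False))))

    calls = pd.DataFrame(
        rows,
        columns=["cell_id", "isotype", "source", "dominant_fraction",
                 "multi_chain_flag"],
    )
    if concordance_pairs:
        conc = pd.crosstab(
            pd.Series([b for b, _ in concordance_pairs], name="bcr_isotype"),
            pd.Series([e for _, e in concordance_pairs], name="expression_isotype"),
        )
    else:
        conc = pd.DataFrame()
    return calls, conc


# --------------------------------------------------------------------------
# clonotyping
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ClonotypeTables:
    """Clone-level table plus the per-cell assignment that produced it."""

    clonotypes: pd.DataFrame
    assignments: pd.DataFrame  # cell_id -> clone_id (+ patient, key)
    n_skipped_rows: int


def _clone_key(row: pd.Series, key_mode: str) -> Optional[str]:
    if key_mode == "junction_aa":
        key = str(row["junction_aa"] or "")
    elif key_mode == "junction_nt":
        key = str(row["junction"] or "")
        if not _NT_RE.match(key):
            return None
    elif key_mode == "vj_junction_aa":
        key = "|".join(str(row[c] or "") for c in ("v_call", "j_call", "junction_aa"))
    else:
        raise ValueError(f"unknown key_mode {key_mode!r}; choose from {KEY_MODES}")
    return key or None


def clone_id_for(patient: str, key: str) -> str:
    return hashlib.sha1(f"{patient}|{key}".encode()).hexdigest()[:12]


def build_clonotypes(
    airr: pd.DataFrame,
    annotation: pd.DataFrame,
    key_mode: str = "junction_aa",
    isotype_calls: Optional[pd.DataFrame] = None,
) -> ClonotypeTables:
    """Group cells into within-patient clonotypes keyed on the junction.

    Rows with empty keys (or non-ACGT junctions in nucleotide mode) are
    skipped and counted. Clone ids are deterministic hashes of
    ``(patient, key)``. When *isotype_calls* is given, each clone carries
    an isotype tally over its non-ambiguous members.
    """
    if key_mode not in KEY_MODES:
        raise ValueError(f"unknown key_mode {key_mode!r}; choose from {KEY_MODES}")
    meta = annotation.set_index("cell_id")
    iso_map = (
        isotype_calls.set_index("cell_id")["isotype"].to_dict()
        if isotype_calls is not None else {}
    )

    igh = airr[(airr["locus"] == "IGH") & _productive_mask(airr)]
    # one chain per cell (highest-UMI productive chain on duplicates)
    igh = igh.groupby("cell_id", sort=True, group_keys=False).apply(
        _pick_igh_row, include_groups=False
    ).reset_index() if len(igh) else igh

    n_skipped = 0
    assign_rows = []
    for _, row in igh.iterrows():
        cell_id = row["cell_id"]
        if cell_id not in meta.index:
            n_skipped += 1
            continue
        key = _clone_key(row, key_mode)
        if key is None:
            n_skipped += 1
            continue
        patient = meta.at[cell_id, "patient"]
        assign_rows.append((cell_id, patient, key, clone_id_for(patient, key)))
    if n_skipped:
        logger.info("build_clonotypes: skipped %d rows (missing/malformed)", n_skipped)

    assignments = pd.DataFrame(
        assign_rows, columns=["cell_id", "patient", "key", "clone_id"]
    )

    clone_rows = []
    for (patient, key), group in assignments.groupby(["patient", "key"], sort=True):
        members = sorted(group["cell_id"])
        sizes_by_comp: dict = {}
        tally: dict = {}
        for cell_id in members:
            comp = (meta.at[cell_id, "tissue"], meta.at[cell_id, "timepoint"])
            comp_key = f"{comp[0]}|{comp[1]}"
            sizes_by_comp[comp_key] = sizes_by_comp.get(comp_key, 0) + 1
            iso = iso_map.get(cell_id)
            if iso and iso != "ambiguous":
                tally[iso] = tally.get(iso, 0) + 1
        size = len(members)
        clone_rows.append(
            {
                "clone_id": clone_id_for(patient, key),
                "patient": patient,
                "key": key,
                "size": size,
                "expanded": size >= 2,
                "members": tuple(members),
                "sizes_by_compartment": sizes_by_comp,
                "n_compartments": len(sizes_by_comp),
                "isotype_tally": tally,
            }
        )
    clonotypes = pd.DataFrame(
        clone_rows,
        columns=["clone_id", "patient", "key", "size", "expanded", "members",
                 "sizes_by_compartment", "n_compartments", "isotype_tally"],
    )
    return ClonotypeTables(clonotypes, assignments, n_skipped)


# --------------------------------------------------------------------------
# expansion & tracking
# --------------------------------------------------------------------------

_QUANTILES = (0.25, 0.5, 0.75, 0.9)


def expansion_summary(
    tables: ClonotypeTables,
    annotation: pd.DataFrame,
    group_by: Sequence[str] = ("response",),
) -> pd.DataFrame:
    """Per-group expanded-cell fractions and clone-size quantiles.

    ``fraction_expanded`` is the share of assigned cells that belong to a
    clone of total size >= 2. Groups with no assigned cells report NaN
    fractions, not zero.
    """
    group_by = list(group_by)
    clone_info = tables.clonotypes.set_index("clone_id")[["size", "expanded"]]
    cells = tables.assignments.merge(annotation, on="cell_id", how="left",
                                     suffixes=("", "_ann"))
    cells = cells.join(clone_info, on="clone_id")

    rows = []
    groups = annotation[group_by].drop_duplicates().itertuples(index=False)
    for grp in groups:
        grp = tuple(grp)
        mask = np.ones(len(cells), dtype=bool)
        for col, val in zip(group_by, grp):
            mask &= (cells[col] == val).to_numpy()
        sub = cells[mask]
        n_cells = len(sub)
        if n_cells == 0:
            rows.append(grp + (0, 0, np.nan) + (np.nan,) * (len(_QUANTILES) + 1))
            continue
        n_exp = int(sub["expanded"].sum())
        # clone-size distribution restricted to the group's cells
        sizes = sub.groupby("clone_id").size().to_numpy()
        qs = tuple(float(np.quantile(sizes, q)) for q in _QUANTILES)
        rows.append(grp + (n_cells, n_exp, n_exp / n_cells) + qs + (float(sizes.max()),))

    cols = group_by + ["n_cells", "n_expanded_cells", "fraction_expanded"]
    cols += [f"clone_size_q{int(q * 100)}" for q in _QUANTILES] + ["clone_size_max"]
    return pd.DataFrame(rows, columns=cols)


def track_shared_clones(tables: ClonotypeTables) -> pd.DataFrame:
    """Clones present in >= 2 (tissue, timepoint) compartments."""
    shared = tables.clonotypes[tables.clonotypes["n_compartments"] >= 2]
    return shared[
        ["clone_id", "patient", "key", "size", "n_compartments",
         "sizes_by_compartment"]
    ].reset_index(drop=True)


def _compartment_values(sizes_by_comp: dict, axis: int) -> set:
    return {k.split("|")[axis] for k in sizes_by_comp}


def clones_spanning_tissues(tracked: pd.DataFrame, *tissues: str) -> pd.DataFrame:
    """Subset of tracked clones with members in every listed tissue."""
    want = set(tissues)
    mask = tracked["sizes_by_compartment"].map(
        lambda d: want <= _compartment_values(d, 0)
    )
    return tracked[mask].reset_index(drop=True)


def clones_spanning_timepoints(tracked: pd.DataFrame, *timepoints: str) -> pd.DataFrame:
    """Subset of tracked clones with members at every listed timepoint."""
    want = set(timepoints)
    mask = tracked["sizes_by_compartment"].map(
        lambda d: want <= _compartment_values(d, 1)
    )
    return tracked[mask].reset_index(drop=True)


def isotype_composition(
    annotation: pd.DataFrame,
    isotype_calls: pd.DataFrame,
    stratify_by: Sequence[str] = ("sample",),
) -> pd.DataFrame:
    """Per-stratum isotype proportions with an explicit ``ambiguous`` column.

    Proportions sum to 1 per stratum over non-ambiguous isotypes plus
    ``ambiguous``; strata with zero called cells are omitted.
    """
    stratify_by = list(stratify_by)
    merged = annotation.merge(isotype_calls[["cell_id", "isotype"]], on="cell_id")
    if merged.empty:
        return pd.DataFrame(columns=stratify_by + list(ISOTYPES) + ["ambiguous"])
    counts = (
        merged.groupby(stratify_by + ["isotype"], sort=True)
        .size()
        .unstack("isotype", fill_value=0)
    )
    for col in list(ISOTYPES) + ["ambiguous"]:
        if col not in counts.columns:
            counts[col] = 0
    counts = counts[list(ISOTYPES) + ["ambiguous"]]
    props = counts.div(counts.sum(axis=1), axis=0)
    return props.reset_index()
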