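"""Configuration-driven orchestration of all analysis stages.

Stages run in dependency order (synthetic -> repertoire -> abundance;
synthetic -> spatial; synthetic -> serology). A single global seed is
fanned out to per-stage child seeds by hashing ``(seed, stage name)``, so
re-running with the same config reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd
import yaml

from . import __version__, abundance, repertoire, serology, spatial
from ._constants import ANTIGEN_CLASSES
from .io import read_table, write_json, write_table
from .synthetic_data import (
    CohortSpec,
    SerologySpec,
    SpatialSpec,
    gen_cohort_repertoire,
    gen_serology,
    gen_spatial_tissue,
)
from .synthetic_data.serology import antigen_panel

logger = logging.getLogger(__name__)

STAGES = ("generate", "repertoire", "abundance", "spatial", "serology")


def default_config() -> dict:
    return {
        "seed": 0,
        "output_dir": "humoralkit_out",
        "stages": {name: True for name in STAGES},
        "inputs": {},
        "synthetic": {"cohort": {}, "spatial": {}, "serology": {}},
        "repertoire": {
            "key_mode": "junction_aa",
            "rescue_min_umis": repertoire.DEFAULT_RESCUE_MIN_UMIS,
            "rescue_min_fraction": repertoire.DEFAULT_RESCUE_MIN_FRACTION,
        },
        "abundance": {"group_col": "response", "reference": "NR",
                      "tissue": "tumor"},
        "spatial": {
            "link_dist_um": spatial.DEFAULT_LINK_DIST_UM,
            "min_community_size": spatial.DEFAULT_MIN_COMMUNITY_SIZE,
            "bandwidth_um": spatial.DEFAULT_BANDWIDTH_UM,
            "k": 10,
            "leiden_resolution": 1.0,
        },
        "serology": {"z_threshold": serology.DEFAULT_Z_THRESHOLD},
    }


def load_config(path: Optional[str] = None, overrides: Optional[dict] = None) -> dict:
    """Merge a YAML config file (and overrides) onto the defaults."""
    config = default_config()
    layers = []
    if path is not None:
        with open(path) as fh:
            layers.append(yaml.safe_load(fh) or {})
    if overrides:
        layers.append(overrides)
    for layer in layers:
        for key, value in layer.items():
            if isinstance(value, dict) and isinstance(config.get(key), dict):
                config[key].update(value)
            else:
                config[key] = value
    return config


def config_hash(config: dict) -> str:
    """Hash of the analytic config; the output location does not count."""
    hashable = {k: v for k, v in config.items() if k != "output_dir"}
    canonical = json.dumps(hashable, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def stage_seed(global_seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little")


def _require_input(config: dict, key: str, fallback: Path) -> Path:
    path = Path(config["inputs"].get(key, fallback))
    if not path.exists():
        raise FileNotFoundError(
            f"required input '{key}' not found at {path}; run the generate "
            f"stage or point inputs.{key} at an existing file"
        )
    return path


def _default_serology_spec(config: dict, outdir: Path, seed: int) -> SerologySpec:
    """Serology spec wired to the generated cohort's patients when present."""
    block = dict(config["synthetic"].get("serology") or {})
    block.setdefault("seed", seed)
    raw_titers = block.pop("true_titers", None)
    spec = SerologySpec(**block)
    if raw_titers is not None:
        titers = {(t["sample"], t["antigen"]): t.get("titer") for t in raw_titers}
        return SerologySpec(**{**block, "true_titers": titers})

    ann_path = outdir / "annotation.csv"
    panel = antigen_panel(spec)
    cta = panel[panel["antigen_class"] == "CTA"]["antigen"].tolist()
    titers: Dict = {}
    hits: Dict = {}
    samples: List[str] = []
    if ann_path.exists():
        ann = read_table(ann_path, sep=",")
        patients = ann[["patient", "response"]].drop_duplicates()
        for _, row in patients.iterrows():
            for tp in ("pre", "post"):
                sample = f"{row['patient']}_plasma_{tp}"
                samples.append(sample)
                responder = row["response"] == "R"
                for i, antigen in enumerate(cta[:3]):
                    if responder:
                        titers[(sample, antigen)] = 200.0 * (4.0 if tp == "post" else 1.0)
                    else:
                        titers[(sample, antigen)] = 50.0 if i == 0 else None
                if responder:
                    hits[(sample, "IgG")] = {"CTA": 3}
    return SerologySpec(
        **{**block, "true_titers": titers, "elispot_samples": tuple(samples),
           "seromics_samples": tuple(samples), "seromics_hits": hits}
    )


def run_pipeline(config: dict, outdir: Optional[str] = None) -> dict:
    """Execute enabled stages; return (and write) the run manifest."""
    outdir = Path(outdir or config["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    chash = config_hash(config)
    meta = {"config_hash": chash, "seed": seed}
    manifest: dict = {
        "config_hash": chash,
        "seed": seed,
        "version": __version__,
        "stages": {},
    }

    def record(stage: str, outputs: Dict[str, pd.DataFrame]):
        manifest["stages"][stage] = {
            "skipped": False,
            "outputs": {name: int(len(df)) for name, df in outputs.items()},
        }

    enabled = config["stages"]

    # ---- generate ---------------------------------------------------------
    if enabled.get("generate", True):
        gseed = stage_seed(seed, "generate")
        cohort_block = dict(config["synthetic"].get("cohort") or {})
        cohort_block.setdefault("seed", gseed)
        if "cluster_baseline_props" in cohort_block:
            cohort_block["cluster_baseline_props"] = dict(
                cohort_block["cluster_baseline_props"]
            )
        cohort_spec = CohortSpec(**{**cohort_block,
                                    "tissues": tuple(cohort_block.get(
                                        "tissues", CohortSpec().tissues))})
        annotation, airr, ighc, registry = gen_cohort_repertoire(cohort_spec)

        spatial_block = dict(config["synthetic"].get("spatial") or {})
        spatial_block.setdefault("seed", gseed)
        spatial_spec = SpatialSpec(**spatial_block)
        cells, truth = gen_spatial_tissue(spatial_spec)

        write_table(annotation, outdir / "annotation.csv", sep=",", **meta)
        write_table(airr, outdir / "rearrangements.airr.tsv", **meta)
        write_table(ighc, outdir / "ighc_umis.csv", sep=",", **meta)
        spatial_df = cells.copy()
        spatial_df["truth_community"] = truth
        write_table(spatial_df, outdir / "spatial_cells.csv", sep=",", **meta)
        write_json(registry, outdir / "ground_truth.json")

        serology_spec = _default_serology_spec(config, outdir, gseed)
        elisa, elispot, seromics = gen_serology(serology_spec)
        write_table(elisa, outdir / "elisa.csv", sep=",", **meta)
        write_table(elispot, outdir / "elispot.csv", sep=",", **meta)
        write_table(seromics, outdir / "seromics.csv", sep=",", **meta)
        record("generate", {
            "annotation.csv": annotation, "rearrangements.airr.tsv": airr,
            "ighc_umis.csv": ighc, "spatial_cells.csv": spatial_df,
            "elisa.csv": elisa, "elispot.csv": elispot, "seromics.csv": seromics,
        })
    else:
        manifest["stages"]["generate"] = {"skipped": True}

    # ---- repertoire -------------------------------------------------------
    isotype_calls = None
    annotation = None
    if enabled.get("repertoire", True):
        rcfg = config["repertoire"]
        annotation = read_table(
            _require_input(config, "annotation", outdir / "annotation.csv"), sep=",")
        airr = read_table(
            _require_input(config, "airr", outdir / "rearrangements.airr.tsv"))
        airr["c_call"] = airr["c_call"].fillna("")
        ighc = read_table(
            _require_input(config, "ighc", outdir / "ighc_umis.csv"), sep=",")

        isotype_calls, concordance = repertoire.assign_isotypes(
            airr, ighc,
            rescue_min_umis=rcfg["rescue_min_umis"],
            rescue_min_fraction=rcfg["rescue_min_fraction"],
        )
        tables = repertoire.build_clonotypes(
            airr, annotation, key_mode=rcfg["key_mode"],
            isotype_calls=isotype_calls,
        )
        expansion = repertoire.expansion_summary(
            tables, annotation, group_by=("response", "cluster"))
        tracked = repertoire.track_shared_clones(tables)
        composition = repertoire.isotype_composition(
            annotation, isotype_calls, stratify_by=("sample", "response"))

        clone_out = tables.clonotypes.copy()
        clone_out["members"] = clone_out["members"].map(lambda m: ";".join(m))
        clone_out["sizes_by_compartment"] = clone_out["sizes_by_compartment"].map(
            json.dumps)
        clone_out["isotype_tally"] = clone_out["isotype_tally"].map(json.dumps)
        tracked_out = tracked.copy()
        tracked_out["sizes_by_compartment"] = tracked_out["sizes_by_compartment"].map(
            json.dumps)

        write_table(isotype_calls, outdir / "isotype_calls.tsv", **meta)
        write_table(concordance.reset_index(), outdir / "isotype_concordance.tsv",
                    **meta)
        write_table(clone_out, outdir / "clonotypes.tsv", **meta)
        write_table(expansion, outdir / "expansion_summary.tsv", **meta)
        write_table(tracked_out, outdir / "shared_clones.tsv", **meta)
        write_table(composition, outdir / "isotype_composition.tsv", **meta)
        record("repertoire", {
            "isotype_calls.tsv": isotype_calls, "clonotypes.tsv": clone_out,
            "expansion_summary.tsv": expansion, "shared_clones.tsv": tracked_out,
            "isotype_composition.tsv": composition,
        })
    else:
        manifest["stages"]["repertoire"] = {"skipped": True}

    # ---- abundance --------------------------------------------------------
    if enabled.get("abundance", True):
        acfg = config["abundance"]
        if annotation is None:
            annotation = read_table(
                _require_input(config, "annotation", outdir / "annotation.csv"),
                sep=",")
        counts, category_cols = abundance.composition_from_annotation(annotation)
        focus = counts[counts["tissue"] == acfg["tissue"]].reset_index(drop=True)
        table, global_test = abundance.differential_abundance(
            focus, category_cols, group_col=acfg["group_col"],
            reference=acfg["reference"],
        )
        enrichment = abundance.tumor_enrichment(counts, category_cols)
        write_table(table, outdir / "differential_abundance.tsv", **meta)
        write_table(enrichment, outdir / "tumor_enrichment.tsv", **meta)
        write_json(global_test, outdir / "abundance_global_test.json")
        record("abundance", {"differential_abundance.tsv": table,
                             "tumor_enrichment.tsv": enrichment})
    else:
        manifest["stages"]["abundance"] = {"skipped": True}

    # ---- spatial ----------------------------------------------------------
    if enabled.get("spatial", True):
        scfg = config["spatial"]
        cells = read_table(
            _require_input(config, "spatial_cells", outdir / "spatial_cells.csv"),
            sep=",")
        communities = spatial.detect_tls_communities(
            cells, link_dist_um=scfg["link_dist_um"],
            min_community_size=scfg["min_community_size"],
        )
        membership_rows = [
            (com.community_id, int(i)) for com in communities for i in com.members
        ]
        membership = pd.DataFrame(membership_rows,
                                  columns=["community_id", "cell_index"])
        for com in communities:
            if com.size >= 3:
                spatial.radial_profile(com, cells,
                                       bandwidth_um=scfg["bandwidth_um"])
        profiles = spatial.profiles_long_table(communities)
        scores, patient_mean = spatial.infiltration_scores(
            cells, k=scfg["k"], leiden_resolution=scfg["leiden_resolution"],
            seed=seed,
        )
        write_table(membership, outdir / "tls_membership.csv", sep=",", **meta)
        write_table(profiles, outdir / "ring_profiles.tsv", **meta)
        write_table(scores, outdir / "infiltration_scores.tsv", **meta)
        write_json({"patient_mean_infiltration": patient_mean},
                   outdir / "infiltration_summary.json")
        record("spatial", {"tls_membership.csv": membership,
                           "ring_profiles.tsv": profiles,
                           "infiltration_scores.tsv": scores})
    else:
        manifest["stages"]["spatial"] = {"skipped": True}

    # ---- serology ---------------------------------------------------------
    if enabled.get("serology", True):
        zcfg = config["serology"]
        elisa = read_table(
            _require_input(config, "elisa", outdir / "elisa.csv"), sep=",")
        elispot = read_table(
            _require_input(config, "elispot", outdir / "elispot.csv"), sep=",")
        seromics = read_table(
            _require_input(config, "seromics", outdir / "seromics.csv"), sep=",")

        titers = serology.titer_table(elisa)
        spots = serology.elispot_table(elispot)
        hits = serology.seromics_hits(seromics, z_threshold=zcfg["z_threshold"])
        sample_ann = _plasma_sample_annotation(hits["sample"].unique())
        hit_counts, hit_tests = serology.hit_class_summary(hits, sample_ann)

        write_table(titers, outdir / "titers.tsv", **meta)
        write_table(spots, outdir / "elispot_calls.tsv", **meta)
        write_table(hits, outdir / "seromics_hits.tsv", **meta)
        write_table(hit_counts, outdir / "hit_class_counts.tsv", **meta)
        write_json(
            {f"{row.channel}:{row.antigen_class}":
             (None if pd.isna(row.p_value) else row.p_value)
             for row in hit_tests.itertuples()},
            outdir / "hit_class_tests.json",
        )
        record("serology", {"titers.tsv": titers, "elispot_calls.tsv": spots,
                            "seromics_hits.tsv": hits,
                            "hit_class_counts.tsv": hit_counts})
    else:
        manifest["stages"]["serology"] = {"skipped": True}

    write_json(manifest, outdir / "manifest.json")
    return manifest


def _plasma_sample_annotation(samples) -> pd.DataFrame:
    """Recover (patient, timepoint, response) from generated sample names."""
    rows = []
    for sample in samples:
        parts = str(sample).split("_")
        patient = parts[0]
        timepoint = parts[-1] if parts[-1] in ("pre", "post") else "pre"
        response = "R" if patient.startswith("R") else "NR"
        rows.append((sample, patient, timepoint, response))
    return pd.DataFrame(rows, columns=["sample", "patient", "timepoint", "response"])


# --------------------------------------------------------------------------
# report
# --------------------------------------------------------------------------

def write_report(outdir: str | Path, manifest: Optional[dict] = None) -> Path:
    """Render a markdown summary of every stage's key outputs."""
    outdir = Path(outdir)
    if manifest is None:
        with open(outdir / "manifest.json") as fh:
            manifest = json.load(fh)

    lines = [
        "# Pipeline report",
        "",
        f"- config hash: `{manifest['config_hash']}`",
        f"- seed: {manifest['seed']}",
        f"- version: {manifest['version']}",
        "",
    ]

    def section(title: str, stage: str, renderer) -> None:
        lines.append(f"## {title}")
        info = manifest["stages"].get(stage, {"skipped": True})
        if info.get("skipped"):
            lines.append("")
            lines.append("_not run_")
            lines.append("")
            return
        renderer()
        lines.append("")

    def table_md(df: pd.DataFrame, max_rows: int = 30) -> List[str]:
        df = df.head(max_rows)
        header = "| " + " | ".join(map(str, df.columns)) + " |"
        rule = "| " + " | ".join("---" for _ in df.columns) + " |"
        body = [
            "| " + " | ".join(
                f"{v:.4g}" if isinstance(v, float) else str(v) for v in row
            ) + " |"
            for row in df.itertuples(index=False)
        ]
        return [header, rule] + body

    def render_repertoire() -> None:
        comp = read_table(outdir / "isotype_composition.tsv")
        by_response = comp.drop(columns=["sample"]).groupby("response").mean()
        lines.append("")
        lines.append("### Isotype composition by response group")
        lines.extend(table_md(by_response.reset_index()))
        lines.append("")
        lines.append("### Expansion")
        lines.extend(table_md(read_table(outdir / "expansion_summary.tsv")))

    def render_abundance() -> None:
        lines.append("")
        lines.append("### Differential abundance (responder vs non-responder)")
        lines.extend(table_md(read_table(outdir / "differential_abundance.tsv")))

    def render_spatial() -> None:
        scores = read_table(outdir / "infiltration_scores.tsv")
        lines.append("")
        lines.append(f"Communities: {len(scores)}; mean infiltration score: "
                     f"{scores['infiltration_score'].mean():.4f}")

    def render_serology() -> None:
        titers = read_table(outdir / "titers.tsv")
        hits = read_table(outdir / "hit_class_counts.tsv")
        lines.append("")
        lines.append(f"Seropositive curves: {int(titers['positive'].sum())} "
                     f"of {len(titers)}")
        lines.append("")
        lines.append("### Seromics hits by class")
        lines.extend(table_md(hits))

    section("Repertoire", "repertoire", render_repertoire)
    section("Differential abundance", "abundance", render_abundance)
    section("Spatial infiltration", "spatial", render_spatial)
    section("Serology", "serology", render_serology)

    path = outdir / "report.md"
    path.write_text("\n".join(lines) + "\n")
    return path
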