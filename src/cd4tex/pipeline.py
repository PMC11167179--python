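"""End-to-end orchestration: simulate -> QC -> normalize -> HVG -> PCA ->
cluster -> markers -> annotate -> panels -> scores -> Tex calls ->
repertoire -> group statistics -> in-vivo layer -> planted-truth evaluation.

Every stage is independently invocable on the previous stage's on-disk
outputs (small CSV/JSON checkpoints; matrices are re-derived from the
simulated counts, which is deterministic and cheap). A single global seed is
threaded through all stages, so identical configs give byte-identical runs.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.metrics import adjusted_rand_score, balanced_accuracy_score

from . import annotate as ann
from . import invivo as iv
from . import preprocess as pp
from . import repertoire as rep
from . import scoring as sc
from . import synthdata as sd
from .io_10x import read_10x, read_contigs, write_10x

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline parameters plus the global seed."""

    seed: int = 0
    sim: sd.SimConfig = field(default_factory=sd.SimConfig)
    qc: pp.QCParams = field(default_factory=pp.QCParams)
    n_hvg: int = 2000
    n_pcs: int = 20
    n_neighbors: int = 20
    resolution: float = 1.0
    marker_top_k: int = 20
    panel_k: int = 30
    n_bins: int = 24
    n_ctrl: int = 100
    clonotype_include_cdr3: bool = False
    volume_mode: str = "width_squared"
    n_mice_per_arm: int = 8
    ratio_volume_corr: float = -0.9

    def __post_init__(self) -> None:
        # the global seed drives every stage, including the simulator
        self.sim.seed = self.seed

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        sim = sd.SimConfig(**raw.pop("sim", {}))
        qc = pp.QCParams(**raw.pop("qc", {}))
        known = set(cls.__dataclass_fields__) - {"sim", "qc"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(sim=sim, qc=qc, **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


# ---------------------------------------------------------------------------
# stages


def stage_simulate(run_dir: Path, config: RunConfig) -> None:
    run_dir = Path(run_dir)
    (run_dir / "sim").mkdir(parents=True, exist_ok=True)
    matrix, truth = sd.simulate_counts(config.sim)
    write_10x(matrix, run_dir / "sim")
    contigs = sd.simulate_contigs(truth, config.sim)
    contigs.to_csv(run_dir / "sim" / "filtered_contig_annotations.csv", index=False)
    truth.to_frame().to_csv(run_dir / "sim" / "ground_truth.csv", index=False)
    with open(run_dir / "sim" / "panels.json", "w") as fh:
        json.dump(
            {"anchors": truth.anchors, "panel_membership": truth.panel_membership,
             "marker_membership": truth.marker_membership},
            fh, indent=2, sort_keys=True,
        )
    tables = sd.simulate_invivo(
        n_mice_per_arm=config.n_mice_per_arm, seed=config.seed,
        ratio_volume_corr=config.ratio_volume_corr,
    )
    tables.measurements.to_csv(run_dir / "sim" / "invivo_measurements.csv", index=False)
    tables.tex_ratios.to_csv(run_dir / "sim" / "invivo_tex_ratios.csv", index=False)
    logger.info("simulate: %d cells x %d genes, %d contig rows",
                matrix.n_cells, matrix.n_genes, len(contigs))


def _context(run_dir: Path, config: RunConfig, state: dict | None = None) -> dict:
    """Load (or reuse) the QC'd, normalized matrix derived from sim counts."""
    if state is None:
        state = {}
    if "norm" not in state:
        counts = read_10x(Path(run_dir) / "sim")
        filtered, qc = pp.qc_filter(counts, config.qc)
        state["counts"] = filtered
        state["qc"] = qc
        state["norm"] = pp.lognormalize(filtered)
    return state


def stage_preprocess(run_dir: Path, config: RunConfig, state: dict | None = None) -> dict:
    run_dir = Path(run_dir)
    state = _context(run_dir, config, state)
    state["qc"].to_csv(run_dir / "qc_metrics.csv", index=False)
    hvg = pp.select_hvg(state["counts"], n=min(config.n_hvg, state["counts"].n_genes))
    emb = pp.pca_embed(state["norm"], hvg, k=config.n_pcs)
    labels = pp.cluster_cells(emb, n_neighbors=config.n_neighbors,
                              resolution=config.resolution, seed=config.seed)
    markers = pp.rank_markers(state["norm"], labels)
    state.update(hvg=hvg, embedding=emb, labels=labels, markers=markers)
    pd.Series(hvg, name="gene").to_csv(run_dir / "hvg.csv", index=False)
    pd.DataFrame({"cell_id": state["norm"].cell_ids, "cluster_id": labels}).to_csv(
        run_dir / "clusters.csv", index=False)
    markers.to_csv(run_dir / "markers.csv", index=False)
    logger.info("preprocess: %d cells kept, %d clusters",
                state["norm"].n_cells, len(set(labels)))
    return state


def stage_annotate(run_dir: Path, config: RunConfig, state: dict | None = None) -> dict:
    run_dir = Path(run_dir)
    state = _context(run_dir, config, state)
    if "labels" not in state:
        state["labels"] = pd.read_csv(run_dir / "clusters.csv")["cluster_id"].to_numpy()
        state["markers"] = pd.read_csv(run_dir / "markers.csv")
    meta_of_cluster = ann.assign_meta_clusters(state["norm"], state["labels"])
    meta = np.array([meta_of_cluster[int(c)] for c in state["labels"]], dtype=object)
    module = ann.assign_modules(meta)
    state.update(meta_of_cluster=meta_of_cluster, meta=meta, module=module)
    pd.DataFrame(
        {"cluster_id": list(meta_of_cluster), "meta_cluster": list(meta_of_cluster.values())}
    ).to_csv(run_dir / "cluster_annotation.csv", index=False)
    ordered, corr = ann.reorder_feature_matrix(state["norm"], state["markers"],
                                               top_k=config.marker_top_k)
    corr.to_csv(run_dir / "feature_module_correlation.csv")
    logger.info("annotate: meta-cluster sizes %s", pd.Series(meta).value_counts().to_dict())
    return state


def stage_score(run_dir: Path, config: RunConfig, state: dict | None = None) -> dict:
    run_dir = Path(run_dir)
    state = _context(run_dir, config, state)
    if "meta" not in state:
        clusters = pd.read_csv(run_dir / "clusters.csv")
        annot = pd.read_csv(run_dir / "cluster_annotation.csv")
        meta_of_cluster = dict(zip(annot["cluster_id"], annot["meta_cluster"]))
        state["labels"] = clusters["cluster_id"].to_numpy()
        state["meta"] = np.array([meta_of_cluster[int(c)] for c in state["labels"]], dtype=object)
        state["module"] = ann.assign_modules(state["meta"])
    norm = state["norm"]
    meta, module = state["meta"], state["module"]
    m1 = module == 1
    m2 = module == 2
    tfh = meta == "Tfh"

    panels = {
        "module1_exhaustion": sc.derive_anchor_panel(
            norm, m1, sd.ANCHORS["module1_exhaustion"], k=config.panel_k,
            name="module1_exhaustion"),
        "module2_exhaustion": sc.derive_anchor_panel(
            norm, m2, sd.ANCHORS["module2_exhaustion"], k=config.panel_k,
            name="module2_exhaustion"),
    }
    cells = pd.DataFrame({"cell_id": norm.cell_ids, "meta_cluster": meta,
                          "module": ["none" if m is None else str(m) for m in module]})
    cells["exhaustion_score"] = np.nan
    cells["tex_flag"] = "NA"
    for mod, mask, pname in ((1, m1, "module1_exhaustion"), (2, m2, "module2_exhaustion")):
        score = sc.module_score(norm, mask, panels[pname], n_bins=config.n_bins,
                                n_ctrl=config.n_ctrl, seed=config.seed)
        call = sc.classify_tex(score, scope=f"module{mod}")
        idx = np.flatnonzero(mask)
        cells.loc[idx, "exhaustion_score"] = score.values
        cells.loc[idx, "tex_flag"] = call.flags
        state[f"texcall_module{mod}"] = call
    nonnaive = m1 | m2
    fscores = sc.functional_scores(norm, nonnaive, tfh_cells=tfh,
                                   n_bins=config.n_bins, n_ctrl=config.n_ctrl,
                                   seed=config.seed, chemotaxis_k=config.panel_k)
    panels["chemotaxis"] = sc.derive_anchor_panel(
        norm, tfh, sd.ANCHORS["chemotaxis"], k=config.panel_k, name="chemotaxis")
    for name, vec in fscores.items():
        col = f"{name}_score"
        cells[col] = np.nan
        cells.loc[np.flatnonzero(nonnaive), col] = vec.values
    state["cells"] = cells
    state["panels"] = panels

    fixed = sc.fixed_panels()
    with open(run_dir / "panels.json", "w") as fh:
        json.dump({name: p.to_dict() for name, p in {**fixed, **panels}.items()},
                  fh, indent=2, sort_keys=True)
    cells.to_csv(run_dir / "cell_scores.csv", index=False)

    # Tex vs nonTex functional contrasts within each module (Kruskal-Wallis)
    rows = []
    contrasts = [
        ("module2", "suppressive_score", (module == 2)),
        ("module1_effector", "effective_score", (meta == "effector")),
        ("module1_tfh", "chemotaxis_score", tfh),
        ("module1", "exhaustion_score", m1),
        ("module2", "exhaustion_score", m2),
    ]
    for scope, colname, mask in contrasts:
        dfm = cells.loc[np.flatnonzero(mask)]
        groups = dfm["tex_flag"].to_numpy()
        vals = dfm[colname].to_numpy()
        if len(set(groups)) < 2 or min((groups == g).sum() for g in set(groups)) < 2:
            continue
        h, p = sc.compare_scores(vals, groups, test="kruskal_wallis")
        mean_tex = float(vals[groups == "Tex"].mean())
        mean_non = float(vals[groups == "nonTex"].mean())
        rows.append(dict(population=scope, score=colname, test="kruskal_wallis",
                         statistic=h, p=p, mean_tex=mean_tex, mean_nontex=mean_non))
    comp = pd.DataFrame(rows)
    comp.to_csv(run_dir / "score_comparisons.csv", index=False)
    state["score_comparisons"] = comp
    return state


def stage_repertoire(run_dir: Path, config: RunConfig, state: dict | None = None) -> dict:
    run_dir = Path(run_dir)
    state = _context(run_dir, config, state)
    if "cells" not in state:
        state["cells"] = pd.read_csv(run_dir / "cell_scores.csv")
    cells = state["cells"]
    contigs = read_contigs(run_dir / "sim" / "filtered_contig_annotations.csv")
    cell_clon, clonotypes = rep.call_clonotypes(
        contigs, cells["cell_id"], include_cdr3=config.clonotype_include_cdr3)
    clonotypes.to_csv(run_dir / "clonotypes.csv", index=False)
    merged = cells.merge(cell_clon, on="cell_id", how="left")
    merged.to_csv(run_dir / "cell_table.csv", index=False)
    state["cell_table"] = merged

    in_module = merged["module"].isin(["1", "2"]) & merged["expansion_bin"].notna()
    sub = merged.loc[in_module].copy()
    sub["group"] = "module" + sub["module"].astype(str) + "_" + sub["tex_flag"]
    table, _ = rep.expansion_composition(
        sub[["cell_id", "expansion_bin"]], dict(zip(sub["cell_id"], sub["group"])))
    table.to_csv(run_dir / "expansion_table.csv")
    state["expansion_table"] = table

    tests = []
    # module contrast (pooled over exhaustion state) and Tex contrasts per module
    mod_table, _ = rep.expansion_composition(
        sub[["cell_id", "expansion_bin"]],
        dict(zip(sub["cell_id"], "module" + sub["module"].astype(str))))
    chi2, df, p = rep.chisq_compare(mod_table)
    tests.append(dict(contrast="module1_vs_module2", chi2=chi2, df=df, p=p))
    for mod in ("1", "2"):
        t = table.loc[[f"module{mod}_Tex", f"module{mod}_nonTex"]]
        chi2, df, p = rep.chisq_compare(t)
        tests.append(dict(contrast=f"module{mod}_tex_vs_nontex", chi2=chi2, df=df, p=p))
    pd.DataFrame(tests).to_csv(run_dir / "expansion_tests.csv", index=False)
    state["expansion_tests"] = pd.DataFrame(tests)
    return state


def stage_invivo(run_dir: Path, config: RunConfig, state: dict | None = None) -> dict:
    run_dir = Path(run_dir)
    state = state or {}
    meas = pd.read_csv(run_dir / "sim" / "invivo_measurements.csv")
    ratios = pd.read_csv(run_dir / "sim" / "invivo_tex_ratios.csv")
    vols = iv.endpoint_volumes(meas, mode=config.volume_mode)
    vols.to_csv(run_dir / "endpoint_volumes.csv", index=False)
    tukey = iv.tukey_compare(vols)
    tukey.to_csv(run_dir / "tumor_volume_tukey.csv", index=False)
    corr = iv.ratio_volume_correlation(ratios, vols)
    with open(run_dir / "ratio_volume_correlation.json", "w") as fh:
        json.dump({"r": corr.r, "r_squared": corr.r_squared, "p": corr.p,
                   "n": corr.n, "significant": corr.significant}, fh, indent=2)
    state.update(endpoint_volumes=vols, tukey=tukey, ratio_corr=corr)
    return state


def stage_evaluate(run_dir: Path, config: RunConfig, state: dict | None = None) -> dict:
    """Score the pipeline against the simulator's planted truth."""
    run_dir = Path(run_dir)
    state = state or {}
    truth = pd.read_csv(run_dir / "sim" / "ground_truth.csv")
    cell_table = state.get("cell_table")
    if cell_table is None:
        cell_table = pd.read_csv(run_dir / "cell_table.csv")
    with open(run_dir / "sim" / "panels.json") as fh:
        true_panels = json.load(fh)
    with open(run_dir / "panels.json") as fh:
        called_panels = json.load(fh)

    merged = cell_table.merge(truth, on="cell_id", how="left", suffixes=("", "_true"))
    evaluation: dict = {"n_cells_analyzed": int(len(merged))}
    evaluation["meta_cluster_ari"] = float(
        adjusted_rand_score(merged["meta_cluster_true"], merged["meta_cluster"]))
    evaluation["meta_cluster_accuracy"] = float(
        (merged["meta_cluster"] == merged["meta_cluster_true"]).mean())
    for pname in ("module1_exhaustion", "module2_exhaustion", "chemotaxis"):
        planted = set(true_panels["panel_membership"][pname])
        called = set(called_panels[pname]["genes"])
        evaluation[f"{pname}_panel_recovered"] = len(planted & called)
        evaluation[f"{pname}_panel_size"] = len(planted)
    for mod in ("1", "2"):
        sub = merged[(merged["module"].astype(str) == mod) & merged["tex_flag"].isin(["Tex", "nonTex"])]
        if sub["tex"].nunique() == 2:
            evaluation[f"module{mod}_tex_balanced_accuracy"] = float(
                balanced_accuracy_score(sub["tex"], sub["tex_flag"] == "Tex"))
    # clone-size multiset recovery
    called_sizes = sorted(pd.read_csv(run_dir / "clonotypes.csv")["size"].tolist())
    retained = truth[truth["cell_id"].isin(set(cell_table["cell_id"]))]
    true_sizes = sorted(retained["clone_id"].value_counts().tolist())
    evaluation["clone_sizes_match"] = bool(called_sizes == true_sizes)
    with open(run_dir / "evaluation.json", "w") as fh:
        json.dump(evaluation, fh, indent=2, sort_keys=True)
    state["evaluation"] = evaluation
    return state


STAGES = ("simulate", "preprocess", "annotate", "score", "repertoire", "invivo", "evaluate")


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute every stage into ``outdir`` and return the in-memory state.

    A stage failure aborts with the stage name attached; partial outputs are
    retained for inspection.
    """
    run_dir = Path(outdir)
    run_dir.mkdir(parents=True, exist_ok=True)
    with open(run_dir / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    state: dict | None = None
    for stage in STAGES:
        fn = globals()[f"stage_{stage}"]
        try:
            result = fn(run_dir, config) if stage == "simulate" else fn(run_dir, config, state)
            state = result if isinstance(result, dict) else state
        except Exception as exc:  # noqa: BLE001 - annotate the failing stage
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    import cd4tex

    manifest = {
        "package_version": cd4tex.__version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": config.seed,
        "parameters": config.to_dict(),
        "stages": list(STAGES),
    }
    with open(run_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return state or {}
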