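"""Planted-truth simulator for CD4+ T-cell exhaustion-module analyses.

Emulates the statistical structure the downstream pipeline assumes:

* four meta-cluster expression programs (Treg / Tfh / effector / naive),
  each marked by its canonical genes (FOXP3, CXCL13, GZMB, CCR7, ...) plus a
  block of synthetic program markers;
* per-module exhaustion latent factors that co-upregulate an anchor gene
  (PDCD1 in Module 1, TIGIT in Module 2, CXCL13 in Tfh) together with a
  correlated block of partner genes, in exhausted (Tex) cells only;
* Tex-linked suppressive (Treg) and effective (effector) functional programs
  on the fixed gene panels used by the scorer;
* negative-binomial (gamma-Poisson) counts with lognormal library sizes and
  a controlled mitochondrial-fraction tail;
* clonotypes whose size distribution is geometric with a smaller ``p``
  (hence larger clones) for Tex-seeded clones;
* per-mouse caliper time series and Tex-ratio tables with a configurable
  negative correlation between the Module1-Tex / Module2-Tex ratio and
  final tumor volume.

Every random draw flows from a single integer seed, so identical configs
produce byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io_10x import CountMatrix

META_CLUSTERS = ("Treg", "Tfh", "effector", "naive")

# canonical marker genes per program (cluster-annotation dictionary)
MARKER_GENES = {
    "Treg": ["FOXP3", "CTLA4", "IL2RA"],
    "Tfh": ["CXCL13", "TOX2", "BCL6"],
    "effector": ["GZMA", "GZMB", "NKG7", "IFNG"],
    "naive": ["CCR7", "IL7R"],
}
AUX_GENES = {
    "proliferative": ["MKI67", "TYMS", "MCM2"],
    "heat_shock": ["HSPA1A", "HSPA1B"],
}

# fixed functional panels used by the scorer
SUPPRESSIVE_PANEL = ["TGFB1", "IL10", "IL12A", "CTLA4", "IKZF4", "LGALS3", "ENTPD1", "NT5E"]
EFFECTIVE_PANEL = ["IL17A", "CD69", "IFNG", "IL4", "IL5", "IL13", "IL17F", "TNFRSF8", "PALLD", "TNF"]

ANCHORS = {"module1_exhaustion": "PDCD1", "module2_exhaustion": "TIGIT", "chemotaxis": "CXCL13"}

_MITO_NAMES = [
    "MT-ND1", "MT-ND2", "MT-CO1", "MT-CO2", "MT-ATP8", "MT-ATP6", "MT-CO3",
    "MT-ND3", "MT-ND4L", "MT-ND4", "MT-ND5", "MT-ND6", "MT-CYB",
]

_DEFAULT_TEX_FRACTION = {"Treg": 0.5, "Tfh": 0.35, "effector": 0.35, "naive": 0.0}


@dataclass
class SimConfig:
    """Generator configuration; defaults define the reference study conditions."""

    n_cells: int = 3000
    n_genes: int = 5000
    meta_cluster_probs: dict = field(
        default_factory=lambda: {"Treg": 0.40, "Tfh": 0.20, "effector": 0.25, "naive": 0.15}
    )
    #: probability that a cell of each meta-cluster is exhausted; a scalar
    #: applies uniformly to Treg/Tfh/effector (never to naive cells)
    tex_fraction: float | dict = field(default_factory=lambda: dict(_DEFAULT_TEX_FRACTION))
    #: natural-log shift applied, via per-gene loadings, to anchor+panel genes
    #: in Tex cells of the factor's home population
    exhaustion_effect_delta: float = 1.0
    panel_size: int = 30
    #: NB size parameter r (variance = mu + mu^2 / r)
    nb_dispersion: float = 2.0
    libsize_log_mean: float = 0.0
    libsize_log_sd: float = 0.35
    mito_gene_count: int = 13
    high_mito_cell_count: int = 7
    clone_geometric_p_tex: float = 0.3
    clone_geometric_p_nontex: float = 0.9
    seed: int = 0
    # secondary knobs (fixed study conditions, exposed for calibration tests)
    marker_genes_per_program: int = 25
    marker_effect: float = 1.5
    anchor_module_effect: float = 1.0
    baseline_log_mean: float = math.log(0.2)
    baseline_log_sd: float = 1.0
    factor_noise_sd: float = 0.25
    mito_base_fraction: float = 0.015
    #: baseline mean count for anchors, markers and planted panel genes;
    #: receptor/effector transcripts are reliably detected, not drop-out noise
    special_gene_mean: float = 2.0

    def tex_fraction_of(self, meta: str) -> float:
        if isinstance(self.tex_fraction, dict):
            return float(self.tex_fraction.get(meta, 0.0))
        return 0.0 if meta == "naive" else float(self.tex_fraction)

    def validate(self) -> None:
        if self.n_cells <= 0 or self.n_genes <= 0:
            raise ValueError("n_cells and n_genes must be positive")
        probs = [self.meta_cluster_probs.get(m, 0.0) for m in META_CLUSTERS]
        if abs(sum(probs) - 1.0) > 1e-12:
            raise ValueError("meta_cluster_probs must sum to 1")
        if self.exhaustion_effect_delta < 0:
            raise ValueError("exhaustion_effect_delta must be >= 0")
        if self.panel_size < 1:
            raise ValueError("panel_size must be >= 1")
        for m in META_CLUSTERS:
            f = self.tex_fraction_of(m)
            if not 0.0 <= f <= 1.0:
                raise ValueError("tex_fraction must lie in [0, 1]")
        for p in (self.clone_geometric_p_tex, self.clone_geometric_p_nontex):
            if not 0.0 < p <= 1.0:
                raise ValueError("clone geometric parameters must lie in (0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.high_mito_cell_count > self.n_cells:
            raise ValueError("high_mito_cell_count exceeds n_cells")
        named = self._count_named_genes()
        if named > self.n_genes:
            raise ValueError(
                f"n_genes={self.n_genes} too small: {named} genes are needed for "
                "markers, anchors, fixed panels, planted panels and mito genes"
            )

    def _count_named_genes(self) -> int:
        canonical = set()
        for genes in MARKER_GENES.values():
            canonical.update(genes)
        for genes in AUX_GENES.values():
            canonical.update(genes)
        canonical.update(SUPPRESSIVE_PANEL)
        canonical.update(EFFECTIVE_PANEL)
        canonical.update(ANCHORS.values())
        return (
            len(canonical)
            + 3 * self.panel_size
            + 4 * self.marker_genes_per_program
            + self.mito_gene_count
        )


@dataclass
class GroundTruth:
    """Planted per-cell and per-gene truth emitted alongside the counts."""

    cell_ids: list[str]
    cell_meta_cluster: np.ndarray
    cell_tex: np.ndarray
    cell_clone_id: np.ndarray
    #: passthrough covariates (no planted biology): sample of origin,
    #: tumor/normal condition and HPV status
    cell_sample: np.ndarray
    cell_condition: np.ndarray
    cell_hpv: np.ndarray
    #: panel name -> ordered list of planted partner genes (anchors excluded)
    panel_membership: dict
    #: meta-cluster -> marker genes (canonical + synthetic program markers)
    marker_membership: dict
    anchors: dict
    high_mito_cells: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_ids,
                "meta_cluster": self.cell_meta_cluster,
                "tex": self.cell_tex,
                "clone_id": self.cell_clone_id,
                "sample_id": self.cell_sample,
                "condition": self.cell_condition,
                "hpv_status": self.cell_hpv,
                "high_mito": [c in set(self.high_mito_cells) for c in self.cell_ids],
            }
        )


def _build_gene_universe(config: SimConfig):
    """Assemble the symbol list and index sets for all planted structure."""
    symbols: list[str] = []
    seen = set()

    def add(names):
        for n in names:
            if n not in seen:
                seen.add(n)
                symbols.append(n)

    add(ANCHORS.values())
    for m in META_CLUSTERS:
        add(MARKER_GENES[m])
    for genes in AUX_GENES.values():
        add(genes)
    add(SUPPRESSIVE_PANEL)
    add(EFFECTIVE_PANEL)

    panels = {
        "module1_exhaustion": [f"M1X{i:03d}" for i in range(1, config.panel_size + 1)],
        "module2_exhaustion": [f"M2X{i:03d}" for i in range(1, config.panel_size + 1)],
        "chemotaxis": [f"CXG{i:03d}" for i in range(1, config.panel_size + 1)],
    }
    for genes in panels.values():
        add(genes)

    prefix = {"Treg": "TRGM", "Tfh": "TFHM", "effector": "EFFM", "naive": "NVM"}
    extra_markers = {
        m: [f"{prefix[m]}{i:03d}" for i in range(1, config.marker_genes_per_program + 1)]
        for m in META_CLUSTERS
    }
    for genes in extra_markers.values():
        add(genes)

    mito = [_MITO_NAMES[i] if i < len(_MITO_NAMES) else f"MT-EXT{i + 1}" for i in range(config.mito_gene_count)]
    add(mito)

    n_bg = config.n_genes - len(symbols)
    add(f"BG{i:05d}" for i in range(1, n_bg + 1))
    return symbols, panels, extra_markers, mito


def simulate_counts(config: SimConfig) -> tuple[CountMatrix, GroundTruth]:
    """Draw a cells x genes UMI matrix with planted meta-clusters, exhaustion
    factors, clones, and a forced high-mitochondrial-fraction tail.

    Exactly ``config.high_mito_cell_count`` cells end with mitochondrial
    fraction > 0.05; every other cell is capped at <= 0.05, so QC recovery is
    exact by construction.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])

    symbols, panels, extra_markers, mito = _build_gene_universe(config)
    col = {s: i for i, s in enumerate(symbols)}
    n_cells, n_genes = config.n_cells, config.n_genes

    # --- cell-level truth -------------------------------------------------
    probs = np.array([config.meta_cluster_probs.get(m, 0.0) for m in META_CLUSTERS])
    meta_idx = rng.choice(len(META_CLUSTERS), size=n_cells, p=probs)
    meta = np.array(META_CLUSTERS, dtype=object)[meta_idx]
    tex = np.zeros(n_cells, dtype=bool)
    for m in META_CLUSTERS:
        mask = meta == m
        tex[mask] = rng.random(mask.sum()) < config.tex_fraction_of(m)

    # --- per-gene log baseline --------------------------------------------
    log_mu = rng.normal(config.baseline_log_mean, config.baseline_log_sd, n_genes)
    special = set()
    for genes in panels.values():
        special.update(genes)
    special.update(ANCHORS.values())
    special.update(SUPPRESSIVE_PANEL)
    special.update(EFFECTIVE_PANEL)
    for genes in MARKER_GENES.values():
        special.update(genes)
    for g in special:
        log_mu[col[g]] = math.log(config.special_gene_mean)

    log_mu = np.tile(log_mu, (n_cells, 1))

    # --- marker programs ---------------------------------------------------
    marker_membership = {
        m: list(MARKER_GENES[m]) + list(extra_markers[m]) for m in META_CLUSTERS
    }
    for m in META_CLUSTERS:
        rows = np.flatnonzero(meta == m)
        cols = [col[g] for g in marker_membership[m]]
        log_mu[np.ix_(rows, cols)] += config.marker_effect

    # anchors are preferentially expressed in their home population
    module1 = np.isin(meta, ("Tfh", "effector"))
    treg = meta == "Treg"
    tfh = meta == "Tfh"
    effector = meta == "effector"
    log_mu[module1, col["PDCD1"]] += config.anchor_module_effect
    log_mu[treg, col["TIGIT"]] += config.anchor_module_effect

    # --- latent exhaustion / functional factors ----------------------------
    delta = config.exhaustion_effect_delta
    factors = [
        (["PDCD1"] + panels["module1_exhaustion"], module1),
        (["TIGIT"] + panels["module2_exhaustion"], treg),
        (["CXCL13"] + panels["chemotaxis"], tfh),
        (SUPPRESSIVE_PANEL, treg),
        (EFFECTIVE_PANEL, effector),
    ]
    # factor noise scales with delta so delta = 0 is an exact null
    # (no residual co-expression) while delta > 0 keeps the Tex/non-Tex
    # separation realistically imperfect
    for genes, pop in factors:
        a = delta * ((tex & pop) + rng.normal(0.0, config.factor_noise_sd, n_cells))
        loadings = rng.uniform(0.5, 1.0, len(genes))
        loadings[0] = 1.0  # anchor / first gene carries full loading
        cols = [col[g] for g in genes]
        log_mu[:, cols] += np.outer(a, loadings)

    # --- mitochondrial baseline --------------------------------------------
    mito_cols = np.array([col[g] for g in mito])
    nonmito_rate = np.exp(log_mu).sum(axis=1).mean() - np.exp(log_mu[:, mito_cols]).sum(axis=1).mean()
    f = config.mito_base_fraction
    per_gene = f / (1.0 - f) * nonmito_rate / len(mito)
    log_mu[:, mito_cols] = math.log(max(per_gene, 1e-8))

    # --- counts -------------------------------------------------------------
    libsize = rng.lognormal(config.libsize_log_mean, config.libsize_log_sd, n_cells)
    mu = np.exp(log_mu) * libsize[:, None]
    r = config.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mu)).astype(np.int64)
    del mu, log_mu

    # --- deterministic mitochondrial-fraction tail -------------------------
    high_idx = np.sort(rng.choice(n_cells, size=config.high_mito_cell_count, replace=False))
    is_mito = np.zeros(n_genes, dtype=bool)
    is_mito[mito_cols] = True
    nonmito_tot = counts[:, ~is_mito].sum(axis=1)
    mito_tot = counts[:, mito_cols].sum(axis=1)
    high = np.zeros(n_cells, dtype=bool)
    high[high_idx] = True
    for i in range(n_cells):
        nm, m = int(nonmito_tot[i]), int(mito_tot[i])
        cap = nm // 19  # fraction <= 0.05  <=>  mito <= nonmito/19
        if high[i]:
            target = 2 * (nm // 19 + 1)  # fraction ~ 0.095, strictly > 0.05
            if m < target:
                deficit = target - m
                base, rem = divmod(deficit, len(mito_cols))
                add = np.full(len(mito_cols), base, dtype=np.int64)
                add[:rem] += 1
                counts[i, mito_cols] += add
        elif m > cap:
            if cap == 0:
                counts[i, mito_cols] = 0
            else:
                scaled = counts[i, mito_cols] * cap // max(m, 1)
                counts[i, mito_cols] = scaled

    # --- clonotype assignment ----------------------------------------------
    clone_ids = np.empty(n_cells, dtype=object)
    counter = 0
    for flag, p in ((True, config.clone_geometric_p_tex), (False, config.clone_geometric_p_nontex)):
        pool = np.flatnonzero(tex == flag)
        pool = rng.permutation(pool)
        pos = 0
        while pos < pool.size:
            size = int(rng.geometric(p))
            counter += 1
            cid = f"CT{counter:05d}"
            members = pool[pos : pos + size]
            clone_ids[members] = cid
            pos += size

    # passthrough covariates: 4 samples, 3 tumor (alternating HPV) + 1 normal
    sample_idx = rng.integers(0, 4, size=n_cells)
    samples = np.array([f"S{i + 1}" for i in range(4)], dtype=object)[sample_idx]
    condition = np.where(sample_idx < 3, "tumor", "normal").astype(object)
    hpv = np.where(sample_idx % 2 == 0, "HPV+", "HPV-").astype(object)

    cell_ids = [f"CELL{i + 1:05d}-1" for i in range(n_cells)]
    gene_ids = [f"SYNG{i + 1:011d}" for i in range(n_genes)]
    matrix = CountMatrix(
        X=sp.csr_matrix(counts),
        cell_ids=cell_ids,
        gene_ids=gene_ids,
        gene_symbols=symbols,
    )
    truth = GroundTruth(
        cell_ids=cell_ids,
        cell_meta_cluster=meta,
        cell_tex=tex,
        cell_clone_id=clone_ids.astype(str),
        cell_sample=samples,
        cell_condition=condition,
        cell_hpv=hpv,
        panel_membership={k: list(v) for k, v in panels.items()},
        marker_membership=marker_membership,
        anchors=dict(ANCHORS),
        high_mito_cells=[cell_ids[i] for i in high_idx],
    )
    return matrix, truth


_AA = "ACDEFGHIKLMNPQRSTVWY"


def simulate_contigs(truth: GroundTruth, config: SimConfig) -> pd.DataFrame:
    """Emit one TRA and one TRB contig row per cell in the 10x filtered-contig
    CSV dialect; cells sharing a clone id share an identical V(D)J/CDR3 tuple
    and distinct clones never collide on their gene-call key."""
    rng = np.random.default_rng([config.seed, 1])
    clones = pd.unique(truth.cell_clone_id)
    keys_seen = set()
    clone_tuple = {}
    for cid in clones:
        while True:
            trav = f"TRAV{rng.integers(1, 42)}"
            traj = f"TRAJ{rng.integers(1, 62)}"
            trbv = f"TRBV{rng.integers(1, 31)}"
            trbd = f"TRBD{rng.integers(1, 3)}"
            trbj = f"TRBJ{rng.integers(1, 3)}-{rng.integers(1, 8)}"
            key = (trav, traj, trbv, trbd, trbj)
            if key not in keys_seen:
                keys_seen.add(key)
                break
        cdr3a = "CA" + "".join(rng.choice(list(_AA), size=8)) + "F"
        cdr3b = "CASS" + "".join(rng.choice(list(_AA), size=8)) + "F"
        clone_tuple[cid] = (trav, traj, trbv, trbd, trbj, cdr3a, cdr3b)

    rows = []
    for bc, cid in zip(truth.cell_ids, truth.cell_clone_id):
        trav, traj, trbv, trbd, trbj, cdr3a, cdr3b = clone_tuple[cid]
        umis_a = int(rng.integers(2, 12))
        umis_b = int(rng.integers(2, 12))
        rows.append(
            dict(barcode=bc, is_cell="True", contig_id=f"{bc}_contig_1", chain="TRA",
                 v_gene=trav, d_gene="None", j_gene=traj, cdr3=cdr3a,
                 reads=umis_a * 47, umis=umis_a)
        )
        rows.append(
            dict(barcode=bc, is_cell="True", contig_id=f"{bc}_contig_2", chain="TRB",
                 v_gene=trbv, d_gene=trbd, j_gene=trbj, cdr3=cdr3b,
                 reads=umis_b * 47, umis=umis_b)
        )
    return pd.DataFrame(rows)


@dataclass
class ArmEffect:
    """Per-arm planted effects for the in-vivo simulator (log scales)."""

    volume_logmean: float
    ratio_logmean: float


DEFAULT_EFFECT_PROFILE = {
    "control": ArmEffect(volume_logmean=math.log(900.0), ratio_logmean=math.log(0.8)),
    "aPD1": ArmEffect(volume_logmean=math.log(420.0), ratio_logmean=math.log(1.7)),
    "aCTLA4": ArmEffect(volume_logmean=math.log(460.0), ratio_logmean=math.log(1.6)),
}


@dataclass
class InVivoTables:
    measurements: pd.DataFrame  # mouse_id, arm, day, length_mm, width_mm
    tex_ratios: pd.DataFrame  # mouse_id, arm, module1_tex_freq, module2_tex_freq, ratio


def simulate_invivo(
    n_mice_per_arm: int = 8,
    arms: tuple = ("control", "aPD1", "aCTLA4"),
    effect_profile: dict | None = None,
    seed: int = 0,
    ratio_volume_corr: float = -0.9,
    volume_log_sd: float = 0.30,
    ratio_log_sd: float = 0.35,
    days: tuple = (7, 10, 13, 16, 19, 22, 25),
) -> InVivoTables:
    """Generate caliper time series and per-mouse Tex-ratio tables.

    ``ratio_volume_corr`` sets the within-arm correlation between the
    log Module1-Tex/Module2-Tex ratio and log final volume (negative by
    default: mice whose CD4 compartment tilts toward Module-1 exhaustion
    carry smaller tumors).
    """
    if n_mice_per_arm < 2:
        raise ValueError("need at least 2 mice per arm")
    if not -1.0 <= ratio_volume_corr <= 1.0:
        raise ValueError("ratio_volume_corr must lie in [-1, 1]")
    profile = dict(DEFAULT_EFFECT_PROFILE if effect_profile is None else effect_profile)
    rng = np.random.default_rng([seed, 2])
    rho = ratio_volume_corr
    aspect = 1.3
    meas_rows, ratio_rows = [], []
    final_day = max(days)
    for arm in arms:
        eff = profile[arm]
        for i in range(n_mice_per_arm):
            mouse = f"{arm}_m{i + 1:02d}"
            z1, z2, z3 = rng.normal(size=3)
            log_v = eff.volume_logmean + volume_log_sd * z1
            log_r = eff.ratio_logmean + ratio_log_sd * (rho * z1 + math.sqrt(1 - rho**2) * z2)
            v_final = math.exp(log_v)
            ratio = math.exp(log_r)
            m2 = float(np.clip(0.30 * math.exp(0.2 * z3), 0.02, 0.9))
            m1 = ratio * m2
            if m1 > 0.95:
                m1 = 0.95
                ratio = m1 / m2
            k = math.log(max(v_final, 45.0) / 40.0) / (final_day - min(days))
            for day in days:
                v = v_final * math.exp(-k * (final_day - day))
                w = (6.0 * v / (math.pi * aspect)) ** (1.0 / 3.0)
                length = aspect * w
                meas_rows.append(
                    dict(mouse_id=mouse, arm=arm, day=int(day),
                         length_mm=round(length, 2), width_mm=round(w, 2))
                )
            ratio_rows.append(
                dict(mouse_id=mouse, arm=arm,
                     module1_tex_freq=round(m1, 4), module2_tex_freq=round(m2, 4),
                     ratio=round(m1 / m2, 4))
            )
    return InVivoTables(pd.DataFrame(meas_rows), pd.DataFrame(ratio_rows))
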