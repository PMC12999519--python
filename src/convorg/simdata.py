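"""Synthetic cohort generator.

Emulates a multi-form hiPS-cell organoid differentiation cohort: several
genetic forms plus controls, four differentiation days, nested
individual / line / differentiation replicates, negative-binomial counts
driven by module latent factors, per-form log2 effects whose shared
(cross-form) component grows over differentiation time, CNV dosage
shifts, and a planted regulator module coupled (negatively) to a set of
downstream modules.  Companion generators produce a single-cell
reference, an IP-MS bait x prey table, a CROP-seq experiment and a
regulator->target annotation table.  Every generator records its ground
truth so parameter recovery can be tested downstream.

The negative binomial is parameterized by mean and dispersion ``alpha``
with Var = mu + alpha * mu^2 (gamma-Poisson mixture); baseline log2
means are Gaussian on the log scale (i.e. log-normal means).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import CONTROL, CohortCounts

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_cohort",
    "simulate_single_cell_reference",
    "simulate_ipms",
    "simulate_cropseq",
    "simulate_regulator_annotations",
]


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for the synthetic cohort.

    Defaults mirror the cohort structure the pipeline targets: nine
    affected forms plus control, differentiation days 25/50/75/100, a
    convergence schedule that rises over differentiation, and nested
    replicate structure.  Effect SDs are on the log2 scale.
    """

    n_genes: int = 5000
    n_forms: int = 10  # including control
    days: tuple = (25, 50, 75, 100)
    individuals_per_form: int = 3
    control_individuals: int = 25  # control-heavy cohort: ~50 control samples per day
    lines_per_individual: int = 1
    diffs_per_line: int = 2
    n_modules: int = 6
    module_size_range: tuple = (40, 80)
    nb_dispersion: float = 0.15
    convergence_schedule: tuple = (0.1, 0.3, 0.6, 0.9)
    form_effect_sd: float = 0.2
    shared_effect_sd: float = 0.2
    cnv_genes_per_form: int = 10
    cnv_dosage: float = 0.5
    n_cnv_forms: int = 2
    n_regulators: int = 8
    regulator_effect: float = -0.6  # latent coupling of downstream modules to the regulator module
    seed: int = 0
    # generative nuisance structure (log2 scale)
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 1.5
    day_slope_sd: float = 0.3
    module_latent_sd: float = 1.0
    loading_range: tuple = (0.7, 1.3)
    sd_individual: float = 0.3
    sd_line: float = 0.15
    sd_differentiation: float = 0.15
    n_seq_pcs: int = 2
    n_downstream_modules: int = 3

    def __post_init__(self):
        if any(b <= a for a, b in zip(self.days, self.days[1:])):
            raise ValueError("days must be strictly increasing")
        if len(self.convergence_schedule) != len(self.days):
            raise ValueError("convergence_schedule length must equal number of days")
        if any(not (0.0 <= s <= 1.0) for s in self.convergence_schedule):
            raise ValueError("convergence_schedule entries must lie in [0, 1]")
        if self.module_size_range[0] < 3:
            raise ValueError("module sizes must be >= 3")
        if self.cnv_dosage <= 0:
            raise ValueError("cnv_dosage must be positive")
        if self.n_forms < 2:
            raise ValueError("need at least control plus one affected form")

    @property
    def forms(self) -> list:
        return [CONTROL] + [f"F{i}" for i in range(1, self.n_forms)]

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


@dataclass
class SimTruth:
    """Planted parameters recorded by the generators."""

    module_labels: pd.Series = None
    form_effects: np.ndarray = None  # gene x affected-form x day, log2
    affected_forms: list = None
    days: tuple = None
    shared_effect: np.ndarray = None  # gene x day, log2
    cnv_genes: dict = None  # form -> set of genes
    cnv_dosage: float = None
    regulators: set = None
    regulator_targets: dict = None  # regulator -> {target: sign}
    upstream_module: int = None
    downstream_modules: list = None
    genes: list = None
    true_proportions: pd.DataFrame = None
    true_ppi_edges: set = None
    knockdown_fraction: dict = None

    def effect_frame(self, day) -> pd.DataFrame:
        """Planted per-form log2 effects at ``day`` as gene x form DataFrame."""
        d = list(self.days).index(day)
        return pd.DataFrame(
            self.form_effects[:, :, d], index=self.genes, columns=self.affected_forms
        )


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """Negative binomial draw with Var = mu + alpha mu^2 via gamma-Poisson."""
    if alpha < 1e-10:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / alpha, scale=mu * alpha)
    return rng.poisson(lam)


def _module_labels(cfg: SimConfig, rng: np.random.Generator, genes) -> pd.Series:
    labels = np.zeros(cfg.n_genes, dtype=int)
    lo, hi = cfg.module_size_range
    pos = 0
    for m in range(1, cfg.n_modules + 1):
        size = int(rng.integers(lo, hi + 1))
        if pos + size > cfg.n_genes:
            raise ValueError("n_genes too small for requested modules")
        labels[pos : pos + size] = m
        pos += size
    return pd.Series(labels, index=genes, name="module")


def simulate_cohort(config: SimConfig) -> tuple[CohortCounts, SimTruth]:
    """Generate the bulk cohort: counts, nested metadata and ground truth.

    Per-gene log2 mean for sample s at day d:

        base_g + slope_g * x_d + sum_m L_gm z_ms + effect(g, form_s, d)
               + cnv(g, form_s) + u_individual + u_line + u_differentiation

    with effect = (1 - s_d) * form-specific + s_d * shared, where s_d is
    the convergence schedule entry for day d.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    genes = [f"G{i:05d}" for i in range(cfg.n_genes)]
    labels = _module_labels(cfg, rng, genes)

    # ---- sample grid with nested replicate structure
    rows = []
    for fi, form in enumerate(cfg.forms):
        n_ind = cfg.control_individuals if form == CONTROL else cfg.individuals_per_form
        for i in range(n_ind):
            ind = f"{form}_ind{i}"
            sex = "F" if (fi + i) % 2 else "M"
            for l in range(cfg.lines_per_individual):
                line = f"{ind}_line{l}"
                for r in range(cfg.diffs_per_line):
                    diff = f"{line}_diff{r}"
                    batch = f"batch{(i + l + r) % 2}"
                    for day in cfg.days:
                        rows.append(
                            dict(
                                sample_id=f"{diff}_d{day}",
                                individual_id=ind,
                                line_id=line,
                                differentiation_id=diff,
                                day=day,
                                form=form,
                                diagnosis=CONTROL if form == CONTROL else "affected",
                                sex=sex,
                                batch=batch,
                            )
                        )
    samples = pd.DataFrame(rows).set_index("sample_id")
    n_samples = len(samples)
    samples["ancestry_pc1"] = 0.0
    samples["ancestry_pc2"] = 0.0
    for ind, grp in samples.groupby("individual_id"):
        pcs = rng.normal(size=2)
        samples.loc[grp.index, ["ancestry_pc1", "ancestry_pc2"]] = pcs
    for k in range(cfg.n_seq_pcs):
        samples[f"seq_pc{k + 1}"] = rng.normal(size=n_samples)

    # ---- gene-level baselines and day trends
    base = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, cfg.n_genes)
    slope = rng.normal(0.0, cfg.day_slope_sd, cfg.n_genes)
    x_day = {d: i / max(len(cfg.days) - 1, 1) for i, d in enumerate(cfg.days)}

    # ---- module loadings and latent factors (upstream module drives the
    #      downstream ones with negative coupling => repression structure)
    loadings = np.zeros((cfg.n_genes, cfg.n_modules))
    lo, hi = cfg.loading_range
    for m in range(1, cfg.n_modules + 1):
        idx = np.where(labels.values == m)[0]
        loadings[idx, m - 1] = rng.uniform(lo, hi, idx.size)
    upstream = 1
    downstream = list(range(2, 2 + min(cfg.n_downstream_modules, cfg.n_modules - 1)))
    z = rng.normal(0.0, 1.0, (cfg.n_modules, n_samples))
    rho = float(np.clip(cfg.regulator_effect, -0.95, 0.95))
    for m in downstream:
        z[m - 1] = rho * z[upstream - 1] + np.sqrt(1 - rho**2) * z[m - 1]
    z *= cfg.module_latent_sd

    # ---- per-form effects with a day-dependent shared component
    affected = cfg.forms[1:]
    u = rng.normal(0.0, cfg.form_effect_sd, (cfg.n_genes, len(affected)))
    v = rng.normal(0.0, cfg.shared_effect_sd, cfg.n_genes)
    n_days = len(cfg.days)
    effects = np.empty((cfg.n_genes, len(affected), n_days))
    shared = np.empty((cfg.n_genes, n_days))
    for d, s in enumerate(cfg.convergence_schedule):
        shared[:, d] = s * v
        effects[:, :, d] = (1.0 - s) * u + (s * v)[:, None]

    # ---- CNV gene sets (taken from the unassigned pool, disjoint per form)
    cnv_shift = np.log2(cfg.cnv_dosage)
    free = list(labels.index[labels.values == 0])
    cnv_genes: dict = {}
    gidx = {g: i for i, g in enumerate(genes)}
    for form in affected[: cfg.n_cnv_forms]:
        take = min(cfg.cnv_genes_per_form, len(free))
        chosen = [free.pop() for _ in range(take)]
        cnv_genes[form] = set(chosen)

    # ---- regulators (top-loading genes of the upstream module) and targets
    up_idx = np.where(labels.values == upstream)[0]
    order = np.argsort(-loadings[up_idx, upstream - 1])
    regs = [genes[i] for i in up_idx[order[: cfg.n_regulators]]]
    regulator_targets: dict = {r: {} for r in regs}
    if regs:
        for m in downstream:
            for i in np.where(labels.values == m)[0]:
                r = regs[int(rng.integers(len(regs)))]
                regulator_targets[r][genes[i]] = -1
    truth = SimTruth(
        module_labels=labels,
        form_effects=effects,
        affected_forms=affected,
        days=cfg.days,
        shared_effect=shared,
        cnv_genes=cnv_genes,
        cnv_dosage=cfg.cnv_dosage,
        regulators=set(regs),
        regulator_targets=regulator_targets,
        upstream_module=upstream,
        downstream_modules=downstream,
        genes=genes,
    )

    # ---- assemble log2 means and draw counts
    # gene-specific nested intercepts: individuals (and lines, differentiations)
    # deviate per gene, creating real within-group correlation rather than a
    # depth shift that normalization would cancel
    ind_u = {k: rng.normal(0, cfg.sd_individual, cfg.n_genes)
             for k in samples["individual_id"].unique()}
    line_u = {k: rng.normal(0, cfg.sd_line, cfg.n_genes)
              for k in samples["line_id"].unique()}
    diff_u = {k: rng.normal(0, cfg.sd_differentiation, cfg.n_genes)
              for k in samples["differentiation_id"].unique()}
    form_pos = {f: j for j, f in enumerate(affected)}
    day_pos = {d: j for j, d in enumerate(cfg.days)}

    logm = np.empty((cfg.n_genes, n_samples))
    for s, (sid, row) in enumerate(samples.iterrows()):
        d = day_pos[row["day"]]
        col = base + slope * x_day[row["day"]] + loadings @ z[:, s]
        if row["form"] != CONTROL:
            col = col + effects[:, form_pos[row["form"]], d]
            for g in cnv_genes.get(row["form"], ()):
                col[gidx[g]] += cnv_shift
        col += ind_u[row["individual_id"]] + line_u[row["line_id"]] + diff_u[row["differentiation_id"]]
        logm[:, s] = col
    mu = np.exp2(logm)
    counts = _nb_sample(rng, mu, cfg.nb_dispersion)
    counts = pd.DataFrame(counts, index=genes, columns=samples.index)

    warnings = []
    per_form_day = samples.groupby(["form", "day"]).size()
    if (per_form_day < 4).any():
        small = per_form_day[per_form_day < 4]
        warnings.append(
            "fewer than 4 samples for form/day cells: "
            + ", ".join(f"{f}@{d}(n={n})" for (f, d), n in small.items())
        )
    return CohortCounts(counts=counts, samples=samples, warnings=warnings), truth


# -------------------------------------------------------- single cell ref

def simulate_single_cell_reference(
    n_celltypes: int = 4,
    cells_per_type: int = 50,
    markers_per_type: int = 25,
    n_genes: int = 500,
    marker_log2_boost: float = 3.0,
    base_log2_mean: float = 3.0,
    nb_dispersion: float = 0.2,
    seed: int = 0,
):
    """Single-cell reference with type-specific marker elevation.

    Returns ``(counts, labels, specificity, markers)`` where counts is a
    cell x gene DataFrame, labels maps cell -> type, specificity is the
    gene x type mean-CPM share (rows sum to 1) computed from the true
    generative means, and markers maps type -> marker gene set.
    """
    if n_celltypes < 2:
        raise ValueError("need at least 2 cell types")
    if markers_per_type < 5:
        raise ValueError("need at least 5 marker genes per type")
    if n_celltypes * markers_per_type > n_genes:
        raise ValueError("marker sets would overlap: too few genes")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    types = [f"T{t}" for t in range(n_celltypes)]
    base = rng.normal(base_log2_mean, 1.0, n_genes)
    mean_log2 = np.tile(base, (n_celltypes, 1))
    markers: dict = {}
    for t in range(n_celltypes):
        idx = np.arange(t * markers_per_type, (t + 1) * markers_per_type)
        markers[types[t]] = set(genes[i] for i in idx)
        mean_log2[t, idx] += marker_log2_boost
    mu = np.exp2(mean_log2)
    cells, labels = [], []
    for t in range(n_celltypes):
        draw = _nb_sample(rng, np.tile(mu[t], (cells_per_type, 1)), nb_dispersion)
        cells.append(draw)
        labels += [types[t]] * cells_per_type
    counts = pd.DataFrame(
        np.vstack(cells),
        index=[f"cell{i:04d}" for i in range(n_celltypes * cells_per_type)],
        columns=genes,
    )
    labels = pd.Series(labels, index=counts.index, name="celltype")
    cpm = mu / mu.sum(axis=1, keepdims=True) * 1e6
    spec = (cpm / cpm.sum(axis=0, keepdims=True)).T
    specificity = pd.DataFrame(spec, index=genes, columns=types)
    return counts, labels, specificity, markers


# --------------------------------------------------------------- IP-MS

def simulate_ipms(
    n_universe: int = 300,
    n_baits: int = 5,
    network_size: int = 20,
    effect: float = 2.0,
    sigma: float = 0.5,
    detect_prob: float = 1.0,
    seed: int = 0,
):
    """Bait x prey logFC table with a planted connected protein set.

    True-edge (bait, member) cells draw logFC ~ N(effect, sigma), all
    other cells ~ N(0, sigma); each cell is independently zeroed with
    probability 1 - detect_prob (undetected prey).  Returns
    ``(IpmsTable, network_set, true_edges)``.
    """
    from .containers import IpmsTable

    if n_universe <= network_size:
        raise ValueError("universe must be larger than the planted network")
    rng = np.random.default_rng(seed)
    prots = [f"P{i:04d}" for i in range(n_universe)]
    baits = prots[:n_baits]
    network = set(prots[:network_size])  # baits are part of the planted network
    logfc = rng.normal(0.0, sigma, (n_baits, n_universe))
    edges = set()
    for b, bait in enumerate(baits):
        for m in network:
            if m == bait:
                continue
            j = prots.index(m)
            logfc[b, j] = rng.normal(effect, sigma)
            edges.add((bait, m))
    detected = rng.random((n_baits, n_universe)) < detect_prob
    logfc = np.where(detected, logfc, 0.0)
    for b, bait in enumerate(baits):
        logfc[b, prots.index(bait)] = 0.0  # self entries excluded downstream
    table = IpmsTable(logfc=pd.DataFrame(logfc, index=baits, columns=prots))
    return table, network, edges


# -------------------------------------------------------------- CROP-seq

def simulate_cropseq(
    n_targets: int = 5,
    guides_per_target: int = 3,
    n_ntc_guides: int = 4,
    cells_per_guide: int = 30,
    n_genes: int = 300,
    n_replicates: int = 3,
    knockdown_fraction: float = 0.75,
    base_log2_mean: float = 4.0,
    nb_dispersion: float = 0.2,
    grna_umi_mean: float = 40.0,
    frac_low_umi: float = 0.1,
    frac_multi: float = 0.1,
    n_mito_genes: int = 5,
    seed: int = 0,
):
    """CROP-seq style experiment: cell x gene counts + per-cell gRNA UMIs.

    Cells carrying a target's guide express that target gene at
    (1 - knockdown_fraction) of baseline.  A fraction of cells get
    sub-threshold guide UMIs or a second guide of a different target so
    the downstream assignment rules are exercised.  Returns
    ``(counts, grna_umis, guide_map, truth)``; ``grna_umis`` is a long
    table (cell, guide, umi), ``guide_map`` maps guide -> (target,
    is_ntc), ``truth`` records per-cell intended assignment, replicate
    and the knockdown fraction per target.
    """
    if not (0.0 < knockdown_fraction < 1.0):
        raise ValueError("knockdown_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    targets = [f"G{i:05d}" for i in range(n_targets)]
    genes = [f"G{i:05d}" for i in range(n_genes - n_mito_genes)] + [
        f"MT-{i}" for i in range(n_mito_genes)
    ]
    guide_rows = []
    for t in targets:
        for g in range(guides_per_target):
            guide_rows.append((f"{t}_g{g}", t, False))
    for g in range(n_ntc_guides):
        guide_rows.append((f"NTC_g{g}", "NTC", True))
    guide_map = pd.DataFrame(guide_rows, columns=["guide", "target", "is_ntc"]).set_index("guide")

    base = rng.normal(base_log2_mean, 1.0, len(genes))
    mu0 = np.exp2(base)
    cells, umi_rows, truth_rows = [], [], []
    cid = 0
    for guide, row in guide_map.iterrows():
        for _ in range(cells_per_guide):
            cell = f"cell{cid:05d}"
            cid += 1
            rep = f"rep{cid % n_replicates}"
            mu = mu0.copy()
            carried = [guide]
            r = rng.random()
            if r < frac_low_umi:
                umi = int(rng.integers(1, 10))  # below the UMI threshold
            else:
                umi = max(10, int(rng.poisson(grna_umi_mean)))
                if r < frac_low_umi + frac_multi:
                    # add a second guide of a *different* target above threshold
                    others = guide_map.index[guide_map["target"] != row["target"]]
                    other = others[int(rng.integers(len(others)))]
                    carried.append(other)
            for g in carried:
                tgt = guide_map.loc[g, "target"]
                if tgt != "NTC":
                    mu[genes.index(tgt)] *= 1.0 - knockdown_fraction
            umi_rows.append((cell, guide, umi))
            for g in carried[1:]:
                umi_rows.append((cell, g, max(10, int(rng.poisson(grna_umi_mean)))))
            cells.append(_nb_sample(rng, mu, nb_dispersion))
            assigned = row["target"] if (len(carried) == 1 and umi >= 10) else None
            truth_rows.append((cell, row["target"], assigned, rep))
    counts = pd.DataFrame(
        np.vstack(cells), index=[r[0] for r in truth_rows], columns=genes
    )
    grna_umis = pd.DataFrame(umi_rows, columns=["cell", "guide", "umi"])
    truth = pd.DataFrame(
        truth_rows, columns=["cell", "intended_target", "expected_assignment", "replicate"]
    ).set_index("cell")
    truth.attrs["knockdown_fraction"] = {t: knockdown_fraction for t in targets}
    return counts, grna_umis, guide_map, truth


# -------------------------------------------------- regulator annotations

def simulate_regulator_annotations(truth: SimTruth, fpr: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Regulator->target annotation table: planted truth plus false positives.

    Each (regulator, non-target gene) pair is spuriously annotated with
    probability ``fpr``.  All annotations from planted regulators carry
    the high-confidence flag.
    """
    if not (0.0 <= fpr < 1.0):
        raise ValueError("fpr must lie in [0, 1)")
    if truth.regulators is None:
        raise ValueError("truth has no regulators")
    rng = np.random.default_rng(seed)
    rows = []
    for reg in sorted(truth.regulators):
        tgts = truth.regulator_targets.get(reg, {})
        for t in sorted(tgts):
            rows.append((reg, t, True))
        if fpr > 0:
            pool = [g for g in truth.genes if g not in tgts and g != reg]
            hits = np.asarray(pool)[rng.random(len(pool)) < fpr]
            for t in hits:
                rows.append((reg, str(t), True))
    return pd.DataFrame(rows, columns=["regulator", "target", "high_confidence"])
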