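"""Synthetic data with the statistical structure of a pooled-organoid trisomy study.

Everything downstream of sequencing/plate-reading is emulated here: a gene
annotation (with ~1% of genes on chr21), two single-cell-style cluster
expression profiles with a marker table (emulating two independent reference
datasets covering 24 clusters grouped into 13 cell-types), bulk RNA-seq counts
as negative-binomial draws from cell-type mixtures with a chr21 gene-dosage
multiplier in trisomic lines, per-organoid size measurements, and ELISA
optical densities for secreted amyloid-beta with a four-parameter-logistic
response and a trisomy fold effect.

Every generator takes one integer seed and derives per-entity streams from it
hierarchically (one stream per line / batch / pool), so draws for one entity
do not shift when the design is subset. All generators are bit-reproducible
given (config, seed).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CountMatrix
from .design import Design

#: The 13 reference cell-types used for deconvolution (labels as printed in
#: the source atlas metadata, including its two "responsible" spellings).
CELL_TYPES = (
    "Astrocyte",
    "BMP responsible cell",
    "Cilia bearing cell",
    "Cortical neuron",
    "Glia progenitor cell",
    "Intermediate",
    "Interneuron",
    "Mesoderm",
    "Neuroepithelial cell",
    "Neuron",
    "Oligodendrocyte OPC",
    "Proteoglycan expressing cell",
    "Unfolded protein responsible cell",
)

#: Base cell-type composition used as the centre of line propensities: the
#: grand mean of the measured disomic/trisomic average proportions, with a
#: small floor for near-absent types, renormalized.
BASE_COMPOSITION = {
    "Astrocyte": 0.09505,
    "BMP responsible cell": 0.001,
    "Cilia bearing cell": 0.001,
    "Cortical neuron": 0.2475,
    "Glia progenitor cell": 0.1805,
    "Intermediate": 0.001,
    "Interneuron": 0.2905,
    "Mesoderm": 0.0549,
    "Neuroepithelial cell": 0.05575,
    "Neuron": 0.03855,
    "Oligodendrocyte OPC": 0.0217,
    "Proteoglycan expressing cell": 0.00505,
    "Unfolded protein responsible cell": 0.0104,
}


def _stream(seed: int, *labels) -> np.random.Generator:
    """Hierarchical seeding: an independent stream per (seed, label path)."""
    digest = hashlib.sha256(("/".join(map(str, labels))).encode()).digest()
    key = int.from_bytes(digest[:8], "little")
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(key,)))


# ---------------------------------------------------------------------------
# gene annotation


def make_annotation(
    n_genes: int = 2000,
    frac_chr21: float = 0.01,
    frac_ribo_mito: float = 0.02,
    seed: int = 0,
) -> pd.DataFrame:
    """Gene table with chromosome, exonic length (bp), biotype and ribo/mito flag.

    Chromosome 21 carries ``frac_chr21`` of genes (~1% by default, matching
    its share of the genome); the remainder are spread over the other
    autosomes. Exonic lengths are log-normal around ~1.5 kb.
    """
    if n_genes < 100:
        raise ValueError("need at least 100 genes")
    rng = _stream(seed, "annotation")
    n21 = max(1, int(round(frac_chr21 * n_genes)))
    other_chroms = [f"chr{i}" for i in range(1, 21)] + ["chr22", "chrX"]
    chroms = np.array(["chr21"] * n21 + list(rng.choice(other_chroms, size=n_genes - n21)))
    rng.shuffle(chroms)
    lengths = np.exp(rng.normal(np.log(1500.0), 0.6, size=n_genes))
    lengths = np.maximum(lengths, 150.0).round().astype(int)
    biotype = np.where(
        rng.random(n_genes) < 0.85, "protein_coding",
        np.where(rng.random(n_genes) < 0.5, "lincRNA", "processed_pseudogene"),
    )
    # ribo/mito genes never on chr21 so exclusion rules are separable
    ribo_mito = (rng.random(n_genes) < frac_ribo_mito) & (chroms != "chr21")
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    names = np.array(gene_ids, dtype=object)
    rm_idx = np.flatnonzero(ribo_mito)
    for j, i in enumerate(rm_idx):
        prefix = "MT-" if j % 3 == 0 else ("RPL" if j % 3 == 1 else "RPS")
        names[i] = f"{prefix}{i}"
    ann = pd.DataFrame(
        {
            "chromosome": chroms,
            "exonic_length": lengths,
            "biotype": biotype,
            "is_ribo_or_mito": ribo_mito,
        },
        index=pd.Index(names, name="gene_id"),
    )
    return ann


# ---------------------------------------------------------------------------
# single-cell style reference


@dataclass
class ReferenceSimOutput:
    """Two emulated cluster-profile datasets plus marker table and mapping."""

    profiles_A: pd.DataFrame  # genes x clusters
    profiles_B: pd.DataFrame
    marker_table: pd.DataFrame  # gene_id, cluster, p_value, fold_change
    cluster_to_celltype: dict[str, str]
    annotation: pd.DataFrame

    def celltype_profile(self, which: str = "mean") -> pd.DataFrame:
        """Cell-type level profiles: mean over each cell-type's clusters."""
        frames = {"A": self.profiles_A, "B": self.profiles_B}
        if which in frames:
            prof = frames[which]
            cols = {}
            for ct in sorted(set(self.cluster_to_celltype.values())):
                members = [c for c, t in self.cluster_to_celltype.items() if t == ct]
                cols[ct] = prof[members].mean(axis=1)
            return pd.DataFrame(cols)
        a = self.celltype_profile("A")
        b = self.celltype_profile("B")
        return (a + b) / 2.0


def default_cluster_map(n_clusters: int = 24, celltypes=CELL_TYPES) -> dict[str, str]:
    """Assign clusters to cell-types: each type gets one cluster, extras cycle."""
    n_ct = len(celltypes)
    if n_ct > n_clusters:
        raise ValueError("more cell-types than clusters")
    mapping = {}
    for i in range(n_clusters):
        mapping[f"c{i + 1:02d}"] = celltypes[i % n_ct]
    return mapping


def simulate_reference(
    annotation: pd.DataFrame | None = None,
    n_genes: int = 2000,
    n_clusters: int = 24,
    n_celltypes: int = 13,
    markers_per_cluster: int = 40,
    dataset_noise_sd: float = 0.3,
    seed: int = 0,
) -> ReferenceSimOutput:
    """Emulate two independent cluster-level single-cell reference datasets.

    Each cluster receives a disjoint set of marker genes whose expression in
    that cluster exceeds every other cluster by more than the recorded
    fold-change. The two datasets share the underlying profiles and differ by
    per-gene log-normal capture noise, so the marker structure is identical
    in both. With ``dataset_noise_sd`` 0 the two profile matrices are equal.
    """
    if markers_per_cluster < 30:
        raise ValueError("markers_per_cluster must be at least 30")
    if n_celltypes > n_clusters:
        raise ValueError("n_celltypes cannot exceed n_clusters")
    if annotation is None:
        annotation = make_annotation(n_genes=n_genes, seed=seed)
    n_genes = len(annotation)
    if n_clusters * markers_per_cluster > n_genes:
        raise ValueError("not enough genes for the requested marker sets")
    celltypes = CELL_TYPES[:n_celltypes]
    cluster_map = default_cluster_map(n_clusters, celltypes)
    clusters = list(cluster_map)

    rng = _stream(seed, "reference")
    genes = annotation.index.to_numpy()
    base = np.exp(rng.normal(np.log(20.0), 1.0, size=n_genes))  # baseline expression

    # disjoint marker sets per cluster
    perm = rng.permutation(n_genes)
    profiles = np.tile(base[:, None], (1, n_clusters))
    rows = []
    for ci, cluster in enumerate(clusters):
        idx = perm[ci * markers_per_cluster : (ci + 1) * markers_per_cluster]
        fold = rng.uniform(2.0, 6.0, size=markers_per_cluster)
        pvals = np.sort(10 ** rng.uniform(-12, -2, size=markers_per_cluster))
        # actual boost strictly exceeds the reported fold-change
        profiles[idx, ci] = base[idx] * fold * 1.25
        for g, f, p in zip(idx, fold, pvals):
            rows.append((genes[g], cluster, p, f))
    # mild per-cluster jitter on non-marker genes for realism
    marker_idx = perm[: n_clusters * markers_per_cluster]
    nonmarker = np.setdiff1d(np.arange(n_genes), marker_idx)
    profiles[nonmarker] *= np.exp(rng.normal(0.0, 0.1, size=(len(nonmarker), n_clusters)))

    noise_a = np.exp(rng.normal(0.0, dataset_noise_sd, size=n_genes))
    noise_b = np.exp(rng.normal(0.0, dataset_noise_sd, size=n_genes))
    prof_a = pd.DataFrame(profiles * noise_a[:, None], index=annotation.index, columns=clusters)
    prof_b = pd.DataFrame(profiles * noise_b[:, None], index=annotation.index, columns=clusters)
    marker_table = pd.DataFrame(rows, columns=["gene_id", "cluster", "p_value", "fold_change"])
    return ReferenceSimOutput(prof_a, prof_b, marker_table, cluster_map, annotation)


# ---------------------------------------------------------------------------
# bulk counts


@dataclass
class BulkParams:
    """Knobs of the bulk-count mixture simulator.

    dosage: chr21 expression multiplier in trisomic lines (1.5 = one extra
    copy, no compensation). line_propensity_concentration: Dirichlet
    concentration around the base composition for per-line cell-type
    propensities (larger = lines more alike). batch_effect_sd / pool_noise_sd:
    log-scale sd of logistic-normal perturbations of proportions at the
    line x batch and pool levels. gene_noise_sd: log-normal sd of per-gene
    expression multipliers drawn per line and per batch. nb_dispersion:
    negative-binomial dispersion (0 gives the deterministic rounded limit).
    """

    dosage: float = 1.5
    line_propensity_concentration: float = 100.0
    batch_effect_sd: float = 0.10
    pool_noise_sd: float = 0.05
    gene_noise_sd: float = 0.05
    nb_dispersion: float = 0.1
    library_size: float = 1e6
    length_bias: bool = True


@dataclass
class SimTruth:
    """Ground truth recorded by the generators for recovery tests."""

    true_proportions: pd.DataFrame  # samples x cell-types, rows sum to 1
    dosage: pd.Series  # per-gene multiplier applied in trisomic lines
    line_propensity: pd.DataFrame  # lines x cell-types
    abeta_fold: float = 1.0
    de_status: pd.Series | None = None  # injected non-chr21 effects


def _logistic_normal_perturb(p: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Perturb a probability vector on the simplex via additive log-space noise."""
    if sd == 0:
        return p.copy()
    z = np.log(np.maximum(p, 1e-12)) + rng.normal(0.0, sd, size=p.size)
    w = np.exp(z - z.max())
    return w / w.sum()


def simulate_bulk_counts(
    design: Design,
    reference: ReferenceSimOutput,
    params: BulkParams | None = None,
    seed: int = 0,
) -> tuple[CountMatrix, SimTruth]:
    """Negative-binomial bulk counts as cell-type mixtures with chr21 dosage.

    The expected count of gene g in sample s is the library-scaled mixture
    sum_k p_sk T_gk, times the chr21 dosage multiplier when the sample's line
    is trisomic, times per-gene line- and batch-level log-normal noise, times
    a gene-length factor (read counts in bulk RNA-seq scale with exonic
    length, which is why downstream deconvolution FPKM-normalizes).
    Proportions follow a line -> batch -> pool hierarchy: per-line Dirichlet
    propensities around the base composition, perturbed per batch and per
    pool by logistic-normal noise.
    """
    params = params or BulkParams()
    if params.library_size <= 0:
        raise ValueError("library_size must be positive")
    ann = reference.annotation
    celltype_profiles = reference.celltype_profile("mean")
    celltypes = list(celltype_profiles.columns)
    base = np.array([BASE_COMPOSITION.get(ct, 0.01) for ct in celltypes], dtype=float)
    base /= base.sum()

    genes = ann.index
    n_genes = len(genes)
    dosage = pd.Series(1.0, index=genes)
    dosage[ann["chromosome"] == "chr21"] = params.dosage

    lines = design.line_ids
    line_prop = {}
    line_gene_noise = {}
    for line in lines:
        rng_l = _stream(seed, "bulk", "line", line)
        if params.line_propensity_concentration <= 0:
            raise ValueError("line_propensity_concentration must be positive")
        line_prop[line] = rng_l.dirichlet(base * params.line_propensity_concentration)
        line_gene_noise[line] = (
            np.exp(rng_l.normal(0.0, params.gene_noise_sd, size=n_genes))
            if params.gene_noise_sd > 0
            else np.ones(n_genes)
        )
    batches = sorted({s.batch for s in design.samples})
    batch_gene_noise = {}
    batch_prop = {}
    for batch in batches:
        rng_b = _stream(seed, "bulk", "batch", batch)
        batch_gene_noise[batch] = (
            np.exp(rng_b.normal(0.0, params.gene_noise_sd, size=n_genes))
            if params.gene_noise_sd > 0
            else np.ones(n_genes)
        )
        for line in lines:
            rng_lb = _stream(seed, "bulk", "prop", line, batch)
            batch_prop[(line, batch)] = _logistic_normal_perturb(
                line_prop[line], params.batch_effect_sd, rng_lb
            )

    T = celltype_profiles.to_numpy()  # genes x celltypes
    length_factor = (
        (ann["exonic_length"].to_numpy() / 1000.0) if params.length_bias else np.ones(n_genes)
    )
    counts = {}
    props = {}
    for s in design.samples:
        rng_s = _stream(seed, "bulk", "sample", s.sample_id)
        p = _logistic_normal_perturb(batch_prop[(s.line_id, s.batch)], params.pool_noise_sd, rng_s)
        props[s.sample_id] = p
        mix = T @ p
        mu = mix * length_factor * line_gene_noise[s.line_id] * batch_gene_noise[s.batch]
        if s.trisomic:
            mu = mu * dosage.to_numpy()
        mu = mu * (params.library_size / mu.sum())
        if params.nb_dispersion == 0:
            counts[s.sample_id] = np.round(mu).astype(np.int64)
        else:
            shape = 1.0 / params.nb_dispersion
            lam = rng_s.gamma(shape, mu / shape)
            counts[s.sample_id] = rng_s.poisson(lam).astype(np.int64)
    cm = CountMatrix(pd.DataFrame(counts, index=genes), ann)
    truth = SimTruth(
        true_proportions=pd.DataFrame(props, index=celltypes).T,
        dosage=dosage,
        line_propensity=pd.DataFrame(line_prop, index=celltypes).T,
        de_status=pd.Series(False, index=genes),
    )
    return cm, truth


def chr21_read_fraction(counts: CountMatrix, chrom: str = "chr21") -> pd.Series:
    """Per-sample fraction of reads mapping to chr21 genes."""
    mask = counts.is_chr21(chrom).to_numpy()
    return counts.counts.loc[mask].sum(axis=0) / counts.library_sizes


# ---------------------------------------------------------------------------
# organoid sizes


@dataclass
class SizeParams:
    """Log-normal organoid size model: line x batch x residual components.

    Sizes are a generic positive measure (area-like, mm^2). Line means are
    drawn log-uniform over ``line_size_mean_range``; trisomy multiplies line
    means by ``trisomy_size_effect`` (1.0 = no effect, the null the study
    could not reject).
    """

    line_size_mean_range: tuple[float, float] = (2.0, 4.0)
    batch_sd: float = 0.15
    within_pool_cv: float = 0.20
    trisomy_size_effect: float = 1.0

    def __post_init__(self) -> None:
        lo, hi = self.line_size_mean_range
        if lo <= 0 or hi < lo:
            raise ValueError("line_size_mean_range must be positive and ordered")
        if self.batch_sd < 0 or self.within_pool_cv < 0 or self.trisomy_size_effect <= 0:
            raise ValueError("variance components must be >= 0 and effect > 0")


def simulate_organoid_sizes(
    design: Design, params: SizeParams | None = None, seed: int = 0
) -> pd.DataFrame:
    """Per-organoid sizes for the full roster (sequenced and reserved pools)."""
    params = params or SizeParams()
    lo, hi = params.line_size_mean_range
    line_mean = {}
    for line in sorted({o.line_id for o in design.roster}):
        rng_l = _stream(seed, "size", "line", line)
        line_mean[line] = float(np.exp(rng_l.uniform(np.log(lo), np.log(hi))))
    batch_eff = {}
    rows = []
    for o in design.roster:
        key = (o.line_id, o.batch)
        if key not in batch_eff:
            rng_b = _stream(seed, "size", "batch", *key)
            batch_eff[key] = rng_b.normal(0.0, params.batch_sd) if params.batch_sd > 0 else 0.0
        rng_o = _stream(seed, "size", "organoid", o.organoid_id)
        resid = rng_o.normal(0.0, params.within_pool_cv) if params.within_pool_cv > 0 else 0.0
        mean = line_mean[o.line_id] * (params.trisomy_size_effect if o.trisomic else 1.0)
        rows.append(
            {
                "organoid_id": o.organoid_id,
                "line_id": o.line_id,
                "trisomic": o.trisomic,
                "batch": o.batch,
                "pool": o.pool,
                "area": float(mean * np.exp(batch_eff[key] + resid)),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ELISA


def fourpl(x, slope: float, lower: float, upper: float, midpoint: float):
    """Four-parameter log-logistic response: OD as a function of concentration."""
    x = np.asarray(x, dtype=float)
    return lower + (upper - lower) / (1.0 + np.exp(slope * (np.log(x) - np.log(midpoint))))


@dataclass
class CurveParams:
    slope: float = -1.2
    lower: float = 0.05
    upper: float = 3.0
    midpoint: float = 200.0

    def __post_init__(self) -> None:
        if self.upper <= self.lower:
            raise ValueError("upper asymptote must exceed lower")
        if self.midpoint <= 0:
            raise ValueError("midpoint must be positive")


@dataclass
class ElisaParams:
    """ELISA generator: true concentrations, a 4PL plate response, and RNA proxies.

    Concentrations are pg/ml; the trisomy effect multiplies every trisomic
    pool's true concentration by ``abeta_fold``. The cv parameters are
    log-scale standard deviations of multiplicative line, line x batch and
    residual effects. The default calibration series is seven two-fold
    dilutions from 500 pg/ml. With the default midpoint/series, strongly
    secreting trisomic pools can exceed the largest calibration OD, emulating
    the saturation that motivates clamping the fitted upper asymptote.
    """

    base_conc: float = 150.0
    abeta_fold: float = 1.73
    line_cv: float = 0.30
    batch_cv: float = 0.20
    residual_cv: float = 0.20
    rna_base: float = 100.0
    rna_cv: float = 0.20
    rna_effect: float = 0.0  # slope of log2(conc) on centred log2(RNA)
    curve: CurveParams = field(default_factory=CurveParams)
    od_noise_sd: float = 0.02
    calib_concentrations: tuple[float, ...] = (7.8125, 15.625, 31.25, 62.5, 125.0, 250.0, 500.0)

    def __post_init__(self) -> None:
        if self.base_conc <= 0:
            raise ValueError("base_conc must be positive")
        conc = np.asarray(self.calib_concentrations, dtype=float)
        if (conc <= 0).any() or len(set(conc.tolist())) != len(conc):
            raise ValueError("calibration concentrations must be positive and distinct")


@dataclass
class ElisaSimOutput:
    calibration: pd.DataFrame  # concentration, od
    samples: pd.DataFrame  # sample_id, line_id, trisomic, batch, pool, od, rna_concentration
    truth: pd.DataFrame  # sample_id, true_concentration
    abeta_fold: float


def simulate_elisa(
    design: Design, params: ElisaParams | None = None, seed: int = 0
) -> ElisaSimOutput:
    """Optical densities for all sequenced pools plus a calibration series."""
    params = params or ElisaParams()
    rng_cal = _stream(seed, "elisa", "calibration")
    conc = np.asarray(params.calib_concentrations, dtype=float)
    cal_od = fourpl(conc, params.curve.slope, params.curve.lower, params.curve.upper, params.curve.midpoint)
    if params.od_noise_sd > 0:
        cal_od = cal_od + rng_cal.normal(0.0, params.od_noise_sd, size=conc.size)
    calibration = pd.DataFrame({"concentration": conc, "od": cal_od})

    line_eff = {}
    for line in design.line_ids:
        rng_l = _stream(seed, "elisa", "line", line)
        line_eff[line] = np.exp(rng_l.normal(0.0, params.line_cv)) if params.line_cv > 0 else 1.0
    batch_eff = {}
    rows = []
    truth_rows = []
    for s in design.samples:
        key = (s.line_id, s.batch)
        if key not in batch_eff:
            rng_b = _stream(seed, "elisa", "batch", *key)
            batch_eff[key] = (
                np.exp(rng_b.normal(0.0, params.batch_cv)) if params.batch_cv > 0 else 1.0
            )
        rng_s = _stream(seed, "elisa", "sample", s.sample_id)
        resid = np.exp(rng_s.normal(0.0, params.residual_cv)) if params.residual_cv > 0 else 1.0
        rna = params.rna_base * (
            np.exp(rng_s.normal(0.0, params.rna_cv)) if params.rna_cv > 0 else 1.0
        )
        true_conc = params.base_conc * line_eff[s.line_id] * batch_eff[key] * resid
        if s.trisomic:
            true_conc *= params.abeta_fold
        if params.rna_effect != 0:
            true_conc *= 2.0 ** (params.rna_effect * np.log2(rna / params.rna_base))
        od = float(
            fourpl(true_conc, params.curve.slope, params.curve.lower, params.curve.upper, params.curve.midpoint)
        )
        if params.od_noise_sd > 0:
            od += rng_s.normal(0.0, params.od_noise_sd)
        rows.append(
            {
                "sample_id": s.sample_id,
                "line_id": s.line_id,
                "trisomic": s.trisomic,
                "batch": s.batch,
                "pool": s.pool,
                "od": od,
                "rna_concentration": float(rna),
            }
        )
        truth_rows.append({"sample_id": s.sample_id, "true_concentration": float(true_conc)})
    return ElisaSimOutput(
        calibration=calibration,
        samples=pd.DataFrame(rows),
        truth=pd.DataFrame(truth_rows),
        abeta_fold=params.abeta_fold,
    )
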