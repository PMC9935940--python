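"""Cell-type signature construction and dampened-weighted-least-squares deconvolution.

The signature (basis) matrix is built from two independent single-cell
reference datasets covering 24 clusters grouped into 13 cell-types. Marker
genes are ranked per cluster by p-value (ties broken by fold-change, then
gene id): cell-types backed by a single cluster take their top 30 markers;
cell-types spanning several clusters take the top 5 from each constituent
cluster and fill up to 30 from the merged ranked list. Ribosomal and
mitochondrial genes are excluded, as are chr21 genes — the latter so a chr21
dosage effect cannot leak directly into estimated cell-type proportions. Each
dataset's signature column is the cell-type's mean cluster expression on a
CPM scale divided by 100 (a pure rescaling that avoids poorly scaled normal
equations; normalized proportions are invariant to it), and the final basis
averages the two datasets.

Bulk profiles enter on an FPKM scale (length-corrected, so they are
commensurate with length-free single-cell CPM), and proportions are estimated
by dampened weighted least squares: iteratively reweighted non-negative least
squares with per-gene weights 1/fitted^2, capped at a dampening constant
chosen from a power-of-2 grid to stabilize rare cell-types.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .containers import CountMatrix

logger = logging.getLogger(__name__)


@dataclass
class ReferenceBasis:
    """Marker-genes x cell-types signature matrix with selection provenance."""

    S: pd.DataFrame  # genes x cell-types, non-negative
    provenance: pd.DataFrame  # gene_id, celltype, cluster, rank, rule

    @property
    def genes(self) -> pd.Index:
        return self.S.index

    @property
    def celltypes(self) -> list[str]:
        return list(self.S.columns)


@dataclass
class ProportionEstimate:
    sample_id: str
    p: pd.Series  # over cell-types, non-negative, sums to 1
    dampening: float
    iterations: int
    residual_norm: float
    converged: bool


def _rank_markers(rows: pd.DataFrame) -> pd.DataFrame:
    """Order marker rows by p ascending, fold-change descending, gene id."""
    return rows.sort_values(
        ["p_value", "fold_change", "gene_id"], ascending=[True, False, True]
    ).reset_index(drop=True)


def build_basis(
    marker_table: pd.DataFrame,
    profiles_A: pd.DataFrame,
    profiles_B: pd.DataFrame,
    cluster_to_celltype: dict[str, str],
    annotation: pd.DataFrame,
    n_markers: int = 30,
    n_per_cluster_multicluster: int = 5,
    exclude_chr: str | None = "chr21",
    scale_cpm_by_100: bool = True,
) -> ReferenceBasis:
    """Construct the averaged two-dataset signature matrix.

    Ineligible genes (ribosomal/mitochondrial, and genes on ``exclude_chr``)
    are dropped from the ranked marker lists *before* counting, so each
    cell-type still receives up to ``n_markers`` eligible markers.
    """
    for prof, name in ((profiles_A, "profiles_A"), (profiles_B, "profiles_B")):
        missing = set(marker_table["gene_id"]) - set(prof.index)
        if missing:
            raise ValueError(f"{name} does not cover marker genes: {sorted(missing)[:5]} ...")

    ann = annotation
    ineligible = set(ann.index[ann["is_ribo_or_mito"]])
    if exclude_chr is not None:
        ineligible |= set(ann.index[ann["chromosome"] == exclude_chr])

    celltype_clusters: dict[str, list[str]] = {}
    for cluster, ct in cluster_to_celltype.items():
        celltype_clusters.setdefault(ct, []).append(cluster)

    selected: dict[str, list[tuple[str, str, int, str]]] = {}
    for ct, clusters in celltype_clusters.items():
        eligible = marker_table[
            marker_table["cluster"].isin(clusters)
            & ~marker_table["gene_id"].isin(ineligible)
        ]
        if eligible.empty:
            raise ValueError(f"cell-type {ct!r} has no eligible marker genes after exclusions")
        picks: list[tuple[str, str, int, str]] = []
        chosen: set[str] = set()
        if len(clusters) == 1:
            ranked = _rank_markers(eligible)
            for rank, row in ranked.head(n_markers).iterrows():
                picks.append((row["gene_id"], row["cluster"], int(rank), "top30"))
        else:
            for cluster in sorted(clusters):
                ranked = _rank_markers(eligible[eligible["cluster"] == cluster])
                for rank, row in ranked.iterrows():
                    if len([p for p in picks if p[1] == cluster and p[3] == "top5"]) >= n_per_cluster_multicluster:
                        break
                    if row["gene_id"] not in chosen:
                        picks.append((row["gene_id"], cluster, int(rank), "top5"))
                        chosen.add(row["gene_id"])
            merged = _rank_markers(eligible)
            for rank, row in merged.iterrows():
                if len(picks) >= n_markers:
                    break
                if row["gene_id"] not in chosen:
                    picks.append((row["gene_id"], row["cluster"], int(rank), "merged-fill"))
                    chosen.add(row["gene_id"])
        selected[ct] = picks

    prov = pd.DataFrame(
        [
            {"gene_id": g, "celltype": ct, "cluster": cl, "rank": r, "rule": rule}
            for ct, picks in selected.items()
            for (g, cl, r, rule) in picks
        ]
    )
    union_genes = sorted(prov["gene_id"].unique())

    def dataset_signature(profiles: pd.DataFrame) -> pd.DataFrame:
        cpm = profiles / profiles.sum(axis=0) * 1e6
        if scale_cpm_by_100:
            cpm = cpm / 100.0
        cols = {}
        for ct, clusters in celltype_clusters.items():
            cols[ct] = cpm[clusters].mean(axis=1)
        return pd.DataFrame(cols).loc[union_genes]

    S = (dataset_signature(profiles_A) + dataset_signature(profiles_B)) / 2.0
    S = S[sorted(celltype_clusters)]
    S.index.name = "gene_id"
    return ReferenceBasis(S=S, provenance=prov)


def to_fpkm(counts: CountMatrix) -> pd.DataFrame:
    """Fragments per kilobase of exon per million mapped fragments."""
    lengths = counts.annotation["exonic_length"].astype(float)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    lib = counts.library_sizes.astype(float)
    if (lib == 0).any():
        raise ValueError("zero library size")
    return counts.counts.div(lib, axis=1).div(lengths, axis=0) * 1e9


def _wnnls(S: np.ndarray, b: np.ndarray, w: np.ndarray) -> np.ndarray:
    sw = np.sqrt(w)
    sol, _ = nnls(S * sw[:, None], b * sw)
    return sol


def _normalize(p: np.ndarray) -> np.ndarray:
    total = p.sum()
    if total <= 0:
        return np.full(p.size, 1.0 / p.size)
    return p / total


def choose_dampening(
    S: np.ndarray,
    b: np.ndarray,
    weights: np.ndarray,
    grid: tuple[int, ...],
    n_boot: int = 25,
    seed: int = 0,
) -> float:
    """Pick the weight-cap multiplier that gives the most stable solution.

    For each candidate d the per-gene weights are capped at d times the
    smallest positive weight; stability is measured as the total variance of
    the normalized solution across gene-bootstrap resamples. Ties go to the
    smaller constant. Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    pos = weights[weights > 0]
    if pos.size == 0:
        return float(grid[0])
    wmin = pos.min()
    n = b.size
    resamples = [rng.integers(0, n, size=n) for _ in range(n_boot)]
    best_d, best_score = float(grid[0]), np.inf
    for d in grid:
        capped = np.minimum(weights, d * wmin)
        sols = []
        for idx in resamples:
            sols.append(_normalize(_wnnls(S[idx], b[idx], capped[idx])))
        score = float(np.var(np.stack(sols), axis=0).sum())
        if score < best_score - 1e-15:
            best_score, best_d = score, float(d)
    return best_d


def solve_dwls(
    basis: ReferenceBasis,
    bulk: pd.Series,
    dampening_grid: tuple[int, ...] = tuple(2**k for k in range(15)),
    max_iter: int = 100,
    tol: float = 1e-7,
    eps: float = 1e-12,
    n_boot: int = 25,
    seed: int = 0,
    sample_id: str = "sample",
) -> ProportionEstimate:
    """Estimate cell-type proportions for one bulk profile by dampened WLS.

    Starts from the plain non-negative least-squares solution; each iteration
    reweights genes by 1/max(eps, fitted)^2 with weights capped at the chosen
    dampening constant times the smallest positive weight, then re-solves a
    non-negative weighted least-squares problem. Stops when the normalized
    solution moves less than ``tol`` in max-norm. The returned vector is
    normalized to sum to one.
    """
    bulk = bulk.reindex(basis.genes)
    if bulk.isna().any():
        raise ValueError("bulk vector does not cover all basis genes")
    # canonical gene order, so results cannot depend on input row order
    # (the dampening selection bootstraps gene positions)
    order = np.argsort(np.asarray(basis.genes, dtype=object))
    b = bulk.to_numpy(dtype=float)[order]
    if (b < 0).any():
        raise ValueError("negative values in bulk profile")
    S = basis.S.to_numpy(dtype=float)[order]
    if not np.isfinite(S).all() or (S < 0).any():
        raise ValueError("basis must be non-negative and finite")
    if (S.sum(axis=0) == 0).any():
        raise ValueError("basis has an all-zero cell-type column")

    p, _ = nnls(S, b)
    if b.sum() == 0:
        return ProportionEstimate(sample_id, pd.Series(_normalize(p), index=basis.celltypes),
                                  float("nan"), 0, 0.0, True)
    fitted = np.maximum(S @ p, eps)
    w0 = 1.0 / fitted**2
    d = choose_dampening(S, b, w0, dampening_grid, n_boot=n_boot, seed=seed)

    converged = False
    it = 0
    p_norm = _normalize(p)
    for it in range(1, max_iter + 1):
        fitted = np.maximum(S @ p, eps)
        w = 1.0 / fitted**2
        pos = w[w > 0]
        w = np.minimum(w, d * pos.min())
        p_new = _wnnls(S, b, w)
        new_norm = _normalize(p_new)
        delta = np.abs(new_norm - p_norm).max()
        p, p_norm = p_new, new_norm
        if delta < tol:
            converged = True
            break
    resid = float(np.linalg.norm(S @ p - b))
    return ProportionEstimate(
        sample_id=sample_id,
        p=pd.Series(p_norm, index=basis.celltypes),
        dampening=d,
        iterations=it,
        residual_norm=resid,
        converged=converged,
    )


@dataclass
class DeconvolutionResult:
    proportions: pd.DataFrame  # samples x cell-types
    diagnostics: pd.DataFrame  # per-sample dampening, iterations, residual, converged
    failures: dict[str, str] = field(default_factory=dict)


def deconvolve_samples(counts: CountMatrix, basis: ReferenceBasis, **solver_kwargs) -> DeconvolutionResult:
    """FPKM-normalize and deconvolve every sample against the basis.

    Basis genes absent from the count matrix are treated as zero counts (with
    a warning); solver errors on one sample are recorded without aborting the
    rest of the batch.
    """
    fpkm = to_fpkm(counts)
    missing = basis.genes.difference(fpkm.index)
    if len(missing):
        logger.warning("%d basis genes absent from counts; treated as zero", len(missing))
        fpkm = pd.concat(
            [fpkm, pd.DataFrame(0.0, index=missing, columns=fpkm.columns)]
        )
    fpkm = fpkm.loc[basis.genes]
    rows, diags, failures = {}, [], {}
    for sample in fpkm.columns:
        try:
            est = solve_dwls(basis, fpkm[sample], sample_id=str(sample), **solver_kwargs)
        except Exception as exc:  # noqa: BLE001 - per-sample isolation is the contract
            failures[str(sample)] = str(exc)
            continue
        rows[sample] = est.p
        diags.append(
            {
                "sample_id": est.sample_id,
                "dampening": est.dampening,
                "iterations": est.iterations,
                "residual_norm": est.residual_norm,
                "converged": est.converged,
            }
        )
    proportions = pd.DataFrame(rows).T
    proportions.index.name = "sample_id"
    return DeconvolutionResult(
        proportions=proportions, diagnostics=pd.DataFrame(diags), failures=failures
    )
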