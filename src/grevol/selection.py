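"""Codon-model likelihoods, LRTs, and the gated positive-selection screen.

The screen mirrors the standard codeml-style cascade applied clade by clade
to a large receptor family:

1. fit the one-ratio model (M0) to estimate a clade's global omega (dN/dS);
2. only when that omega exceeds a gate (default 0.3) — i.e. purifying
   selection is weak enough for site tests to be informative — compare the
   site-model pair M8 (beta-distributed omega plus a class with
   ``omega_s >= 1``) against M8a (the same with ``omega_s = 1``) by a
   likelihood-ratio test;
3. only when that test is significant, run branch-site model A against its
   ``omega_2 = 1`` null on every terminal branch, correct the branch
   p-values for multiple testing within the clade (q-values), and report
   sites with high posterior probability of the positive-selection class on
   significant branches.

All likelihoods are Felsenstein pruning over the 61 sense codons with the
GY94 rate matrix (:mod:`grevol.codon`), gaps treated as missing data, and
branch lengths re-optimised under every model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import dendropy
import numpy as np
from scipy import optimize, special, stats

from .codon import (
    CODON_INDEX,
    SENSE_CODONS,
    STOP_CODONS,
    f3x4_frequencies,
    gy94_rate_matrix,
    translate,
)
from .enrichment import compute_qvalues

N_CODONS = len(SENSE_CODONS)
GAP = -1


class InvariantAlignmentError(ValueError):
    """The alignment carries no substitutions, so omega is unidentifiable."""


# ---------------------------------------------------------------------------
# Codon alignments

@dataclass
class CodonAlignment:
    """Aligned codon columns over the 61 sense codons; -1 encodes a gap."""

    taxa: list[str]
    codons: np.ndarray  # (n_taxa, n_sites) int

    def __post_init__(self) -> None:
        self.codons = np.asarray(self.codons, dtype=int)
        if self.codons.ndim != 2 or self.codons.shape[0] != len(self.taxa):
            raise ValueError("codon matrix shape must be (n_taxa, n_sites)")
        if self.codons.size and (self.codons.max() >= N_CODONS or self.codons.min() < GAP):
            raise ValueError("codon indices out of range")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return self.codons.shape[1]

    @classmethod
    def from_nucleotides(cls, rows: Mapping[str, str]) -> "CodonAlignment":
        taxa = list(rows)
        lengths = {len(s) for s in rows.values()}
        if len(lengths) != 1:
            raise ValueError("alignment rows differ in length")
        (length,) = lengths
        if length % 3:
            raise ValueError("alignment length not divisible by 3")
        mat = np.full((len(taxa), length // 3), GAP, dtype=int)
        for i, (name, seq) in enumerate(rows.items()):
            seq = seq.upper()
            for j in range(0, length, 3):
                codon = seq[j : j + 3]
                if codon == "---":
                    continue
                if codon in STOP_CODONS:
                    raise ValueError(f"{name}: internal stop codon {codon} at site {j // 3}")
                if codon not in CODON_INDEX:
                    continue  # ambiguous codon -> missing data
                mat[i, j // 3] = CODON_INDEX[codon]
        return cls(taxa=taxa, codons=mat)

    def to_nucleotides(self) -> dict[str, str]:
        out = {}
        for i, name in enumerate(self.taxa):
            out[name] = "".join(
                "---" if c == GAP else SENSE_CODONS[c] for c in self.codons[i]
            )
        return out

    def gap_fraction(self, row: int) -> float:
        return float(np.mean(self.codons[row] == GAP)) if self.n_sites else 0.0


def backtranslate_alignment(
    protein_alignment: Mapping[str, str], cds_map: Mapping[str, str]
) -> CodonAlignment:
    """Thread each CDS onto its aligned protein (PAL2NAL-style).

    Every aligned amino acid becomes its source codon; protein gaps become
    codon gaps.  The ungapped protein must equal the translation of the CDS
    (a trailing stop codon on the CDS is tolerated and dropped).
    """
    rows: dict[str, str] = {}
    for name, prot in protein_alignment.items():
        if name not in cds_map:
            raise KeyError(f"no CDS for aligned protein {name!r}")
        cds = cds_map[name].upper()
        ungapped = prot.replace("-", "")
        if len(cds) % 3:
            raise ValueError(f"{name}: CDS length not divisible by 3")
        aa = translate(cds)
        if aa.endswith("*"):
            aa = aa[:-1]
            cds = cds[:-3]
        if "*" in aa:
            raise ValueError(f"{name}: internal stop codon in CDS")
        if aa != ungapped:
            raise ValueError(
                f"{name}: protein row does not match the CDS translation"
            )
        out = []
        k = 0
        for ch in prot:
            if ch == "-":
                out.append("---")
            else:
                out.append(cds[3 * k : 3 * k + 3])
                k += 1
        rows[name] = "".join(out)
    return CodonAlignment.from_nucleotides(rows)


def drop_gappy_sequences(
    alignment: CodonAlignment, max_gap_fraction: float = 0.5
) -> CodonAlignment:
    """Remove rows gappier than the threshold, then all-gap columns."""
    keep_rows = [
        i for i in range(alignment.n_taxa)
        if alignment.gap_fraction(i) <= max_gap_fraction
    ]
    if not keep_rows:
        raise ValueError("every sequence exceeds the gap-fraction threshold")
    mat = alignment.codons[keep_rows]
    keep_cols = ~np.all(mat == GAP, axis=0)
    return CodonAlignment(
        taxa=[alignment.taxa[i] for i in keep_rows], codons=mat[:, keep_cols]
    )


# ---------------------------------------------------------------------------
# Site-class model description

@dataclass
class SiteClasses:
    """A mixture of omega classes, optionally branch-heterogeneous.

    ``omegas_fg`` (same length as ``omegas``) gives each class's omega on
    the designated foreground branch; ``None`` means branch-homogeneous.
    """

    weights: np.ndarray
    omegas: np.ndarray
    omegas_fg: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, float)
        self.omegas = np.asarray(self.omegas, float)
        if self.omegas_fg is not None:
            self.omegas_fg = np.asarray(self.omegas_fg, float)
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("class weights must sum to 1")
        if np.any(self.weights < 0) or np.any(self.omegas < 0):
            raise ValueError("weights and omegas must be non-negative")


@dataclass
class CodonModelParams:
    """Everything the likelihood needs besides alignment and topology."""

    kappa: float
    site_classes: SiteClasses
    pi: Optional[np.ndarray] = None  # default: F3x4 from the alignment
    foreground_branch: Optional[str] = None


def beta_class_omegas(p: float, q: float, k: int = 10) -> np.ndarray:
    """Discretise Beta(p, q) into ``k`` equal-probability classes.

    Each class is represented by its conditional mean, computed from the
    regularised incomplete beta function.
    """
    edges = stats.beta.ppf(np.linspace(0.0, 1.0, k + 1), p, q)
    upper = special.betainc(p + 1.0, q, edges[1:])
    lower = special.betainc(p + 1.0, q, edges[:-1])
    means = (p / (p + q)) * (upper - lower) * k
    return np.clip(means, 1e-8, 1.0)


def m8_site_classes(p0: float, p: float, q: float, omega_s: float, k: int = 10) -> SiteClasses:
    omegas = np.append(beta_class_omegas(p, q, k), omega_s)
    weights = np.append(np.full(k, p0 / k), 1.0 - p0)
    return SiteClasses(weights=weights, omegas=omegas)


def branch_site_classes(
    p0: float, p1: float, omega0: float, omega2: float
) -> SiteClasses:
    """Branch-site model A classes: 2a/2b proportions follow p0:p1."""
    rest = max(0.0, 1.0 - p0 - p1)
    share = p0 / (p0 + p1) if (p0 + p1) > 0 else 0.5
    weights = np.array([p0, p1, rest * share, rest * (1.0 - share)])
    weights = weights / weights.sum()
    return SiteClasses(
        weights=weights,
        omegas=np.array([omega0, 1.0, omega0, 1.0]),
        omegas_fg=np.array([omega0, 1.0, omega2, omega2]),
    )


# ---------------------------------------------------------------------------
# Likelihood engine

class _TreeIndex:
    """Postorder arrays for one rooted binary topology."""

    def __init__(self, tree: dendropy.Tree, taxa: Sequence[str]):
        nodes = list(tree.postorder_node_iter())
        self.n_nodes = len(nodes)
        idx = {id(n): i for i, n in enumerate(nodes)}
        self.children: list[list[int]] = [[] for _ in nodes]
        self.labels: list[Optional[str]] = [None] * self.n_nodes
        self.leaf_row: dict[int, int] = {}
        self.root = self.n_nodes - 1
        taxa_index = {t: i for i, t in enumerate(taxa)}
        lengths = []
        self.edge_of_node: list[Optional[int]] = [None] * self.n_nodes
        for i, node in enumerate(nodes):
            label = node.taxon.label if node.taxon else node.label
            self.labels[i] = label
            for c in node.child_nodes():
                self.children[i].append(idx[id(c)])
            if node.is_leaf():
                if label not in taxa_index:
                    raise ValueError(f"tree leaf {label!r} absent from the alignment")
                self.leaf_row[i] = taxa_index[label]
            if node.parent_node is not None:
                self.edge_of_node[i] = len(lengths)
                lengths.append(node.edge.length if node.edge.length else 0.1)
        missing = set(taxa_index) - {
            self.labels[i] for i in self.leaf_row
        }
        if missing:
            raise ValueError(f"alignment rows missing from the tree: {sorted(missing)}")
        self.n_edges = len(lengths)
        self.init_lengths = np.asarray(lengths, float)

    def edge_index_for(self, branch_label: str) -> int:
        for i, lab in enumerate(self.labels):
            if lab == branch_label and self.edge_of_node[i] is not None:
                return self.edge_of_node[i]
        raise KeyError(f"no branch leads to a node labelled {branch_label!r}")


class _Engine:
    """Pattern-compressed pruning likelihood with cached eigensystems."""

    def __init__(self, alignment: CodonAlignment, tree: dendropy.Tree,
                 pi: Optional[np.ndarray] = None):
        self.ti = _TreeIndex(tree, alignment.taxa)
        cols = alignment.codons.T  # (sites, taxa)
        patterns, inverse, counts = np.unique(
            cols, axis=0, return_inverse=True, return_counts=True
        )
        self.patterns = patterns  # (n_pat, n_taxa)
        self.counts = counts.astype(float)
        self.site_to_pattern = inverse
        self.n_pat = patterns.shape[0]
        self.pi = f3x4_frequencies(alignment.codons) if pi is None else np.asarray(pi, float)
        # leaf conditional likelihoods, one-hot with ones for gaps
        # leaf observations: a one-hot conditional likelihood means the
        # child term of the pruning product is just a column lookup in P
        self.leaf_obs: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        for node_i, row in self.ti.leaf_row.items():
            obs = patterns[:, row]
            gap_mask = obs == GAP
            self.leaf_obs[node_i] = (np.where(gap_mask, 0, obs), gap_mask)
        self._sys_cache: dict = {}

    def has_variation(self) -> bool:
        for p in self.patterns:
            vals = p[p >= 0]
            if vals.size and np.unique(vals).size > 1:
                return True
        return False

    def _class_system(self, kappa: float, classes: SiteClasses):
        """Cached eigensystems and class->matrix index maps for one
        (kappa, omega-classes, weights) combination."""
        omegas_bg = classes.omegas
        omegas_fg = classes.omegas_fg if classes.omegas_fg is not None else omegas_bg
        key = (
            round(float(kappa), 12),
            tuple(np.round(omegas_bg, 12)),
            tuple(np.round(omegas_fg, 12)),
            tuple(np.round(classes.weights, 12)),
        )
        hit = self._sys_cache.get(key)
        if hit is not None:
            return hit
        distinct, inv = np.unique(
            np.concatenate([omegas_bg, omegas_fg]), return_inverse=True
        )
        k = len(omegas_bg)
        idx_bg, idx_fg = inv[:k], inv[k:]
        qs = np.stack(
            [gy94_rate_matrix(kappa, om, self.pi, scale=False) for om in distinct]
        )
        # shared scaling: background-mixture expected rate = 1 (codeml style)
        rates = -np.einsum("j,kjj->k", self.pi, qs)
        scale = float(np.dot(classes.weights, rates[idx_bg]))
        if scale <= 0:
            scale = 1.0
        qs /= scale
        d_sqrt = np.sqrt(self.pi)
        s = qs * (d_sqrt[None, :, None] / d_sqrt[None, None, :])
        s = (s + s.transpose(0, 2, 1)) / 2.0
        eigval, eigvec = np.linalg.eigh(s)
        left = np.ascontiguousarray(eigvec / d_sqrt[None, :, None])
        right = np.ascontiguousarray(eigvec.transpose(0, 2, 1) * d_sqrt[None, None, :])
        if len(self._sys_cache) > 64:
            self._sys_cache.clear()
        out = (eigval, left, right, idx_bg, idx_fg)
        self._sys_cache[key] = out
        return out

    def site_log_likelihoods(
        self,
        kappa: float,
        classes: SiteClasses,
        branch_lengths: np.ndarray,
        foreground_edge: Optional[int] = None,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Per-pattern, per-class log-likelihoods and the mixture lnL terms.

        Returns ``(class_site_loglik (K, n_pat), pattern_loglik (n_pat,))``.
        """
        w = classes.weights
        k_classes = len(w)
        eigval, left, right, idx_bg, idx_fg = self._class_system(kappa, classes)
        # per-edge transition matrices for all distinct omegas, batched
        p_edges: dict[int, np.ndarray] = {}
        for e in range(self.ti.n_edges):
            t = branch_lengths[e]
            pall = (left * np.exp(eigval * t)[:, None, :]) @ right
            np.clip(pall, 0.0, None, out=pall)
            idx = idx_fg if (foreground_edge is not None and e == foreground_edge) else idx_bg
            p_edges[e] = pall[idx]  # (K, 61, 61)
        # pruning
        partial: list[Optional[np.ndarray]] = [None] * self.ti.n_nodes
        logscale = np.zeros((k_classes, self.n_pat))
        for i in range(self.ti.n_nodes):
            if i in self.leaf_obs:
                continue
            acc = None
            for c in self.ti.children[i]:
                e = self.ti.edge_of_node[c]
                if c in self.leaf_obs:
                    obs, gap_mask = self.leaf_obs[c]
                    term = p_edges[e][:, :, obs].transpose(0, 2, 1).copy()
                    if gap_mask.any():
                        term[:, gap_mask, :] = 1.0
                else:
                    term = np.matmul(partial[c], p_edges[e].transpose(0, 2, 1))
                    partial[c] = None
                acc = term if acc is None else acc * term
            m = acc.max(axis=2)
            m[m <= 0] = 1.0
            acc /= m[:, :, None]
            logscale += np.log(m)
            partial[i] = acc
        root_partial = partial[self.ti.root]
        class_site = logscale + np.log(
            np.maximum(root_partial @ self.pi, 1e-300)
        )
        mix = special.logsumexp(class_site, b=w[:, None], axis=0)
        return class_site, mix

    def log_likelihood(self, kappa, classes, branch_lengths, foreground_edge=None) -> float:
        _, mix = self.site_log_likelihoods(kappa, classes, branch_lengths, foreground_edge)
        return float(np.dot(self.counts, mix))


def codon_log_likelihood(
    alignment: CodonAlignment,
    tree: dendropy.Tree,
    params: CodonModelParams,
    branch_lengths: Optional[Mapping[str, float]] = None,
) -> float:
    """Mixture pruning log-likelihood at the given parameter values.

    ``branch_lengths`` (keyed by child-node label) overrides the lengths on
    the tree; unlisted branches keep their tree lengths.
    """
    engine = _Engine(alignment, tree, pi=params.pi)
    lengths = engine.ti.init_lengths.copy()
    if branch_lengths:
        for label, t in branch_lengths.items():
            lengths[engine.ti.edge_index_for(label)] = t
    fg = (
        engine.ti.edge_index_for(params.foreground_branch)
        if params.foreground_branch is not None
        else None
    )
    return engine.log_likelihood(params.kappa, params.site_classes, lengths, fg)


# ---------------------------------------------------------------------------
# Fitting

_KAPPA_BOUNDS = (0.05, 50.0)
_OMEGA_BOUNDS = (1e-4, 30.0)
_BL_BOUNDS = (1e-6, 30.0)
_TOL = 1e-6


def _minimize(fun, x0, bounds, maxiter=300):
    res = optimize.minimize(
        fun,
        x0,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": maxiter, "ftol": _TOL * 1e-3, "gtol": 1e-6},
    )
    return res


def _multi_start(fun, starts, bounds, maxiter=300):
    best = None
    for x0 in starts:
        res = _minimize(fun, x0, bounds, maxiter)
        if best is None or res.fun < best.fun:
            best = res
    return best


def _jitter(x0, bounds, seed):
    rng = np.random.default_rng(seed)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    jittered = np.asarray(x0) * np.exp(rng.normal(0.0, 0.3, size=len(x0)))
    return np.clip(jittered, lo, hi)


@dataclass
class M0Fit:
    omega: float
    kappa: float
    branch_lengths: np.ndarray
    lnL: float
    converged: bool


def fit_m0(
    alignment: CodonAlignment,
    tree: dendropy.Tree,
    pi: Optional[np.ndarray] = None,
    restarts: int = 1,
    maxiter: int = 300,
) -> M0Fit:
    """Maximum-likelihood fit of the one-ratio (M0) model."""
    engine = _Engine(alignment, tree, pi=pi)
    if not engine.has_variation():
        raise InvariantAlignmentError(
            "alignment has no substitutions: omega cannot be estimated"
        )
    nb = engine.ti.n_edges
    bounds = [_KAPPA_BOUNDS, _OMEGA_BOUNDS] + [_BL_BOUNDS] * nb
    bl0 = np.clip(engine.ti.init_lengths, 1e-4, 10.0)

    def neg(x):
        classes = SiteClasses(weights=np.array([1.0]), omegas=np.array([x[1]]))
        return -engine.log_likelihood(x[0], classes, x[2:])

    starts = [np.concatenate(([2.0, 0.4], bl0))]
    for i in range(1, restarts):
        starts.append(_jitter(starts[0], bounds, seed=1000 + i))
    res = _multi_start(neg, starts, bounds, maxiter)
    return M0Fit(
        omega=float(res.x[1]),
        kappa=float(res.x[0]),
        branch_lengths=res.x[2:].copy(),
        lnL=-float(res.fun),
        converged=bool(res.success),
    )


@dataclass
class M8PairFit:
    lnL_m8: float
    lnL_m8a: float
    p_value: float
    m8_params: dict
    m8a_params: dict


def _m8_like_neg(engine, free_omega_s: bool):
    k = 10

    def neg(x):
        kappa, p0, p, q = x[0], x[1], x[2], x[3]
        omega_s = x[4] if free_omega_s else 1.0
        bl = x[5:] if free_omega_s else x[4:]
        classes = m8_site_classes(p0, p, q, omega_s, k)
        return -engine.log_likelihood(kappa, classes, bl)

    return neg


def fit_m8_pair(
    alignment: CodonAlignment,
    tree: dendropy.Tree,
    pi: Optional[np.ndarray] = None,
    restarts: int = 2,
    maxiter: int = 300,
) -> M8PairFit:
    """Fit M8a and M8 and test positive selection at sites (LRT, df=1).

    M8 is warm-started from the M8a optimum (plus seeded jittered starts),
    which both speeds the fit and guarantees ``lnL_M8 >= lnL_M8a`` since
    M8a is M8 with ``omega_s`` pinned at 1.
    """
    engine = _Engine(alignment, tree, pi=pi)
    if not engine.has_variation():
        raise InvariantAlignmentError(
            "alignment has no substitutions: site models cannot be fitted"
        )
    nb = engine.ti.n_edges
    bl0 = np.clip(engine.ti.init_lengths, 1e-4, 10.0)
    prop_bounds = (1e-4, 1.0 - 1e-4)
    shape_bounds = (0.05, 50.0)

    bounds_null = [_KAPPA_BOUNDS, prop_bounds, shape_bounds, shape_bounds] + [_BL_BOUNDS] * nb
    x0_null = np.concatenate(([2.0, 0.9, 0.5, 1.5], bl0))
    starts = [x0_null] + [
        _jitter(x0_null, bounds_null, seed=2000 + i) for i in range(1, restarts)
    ]
    res_null = _multi_start(_m8_like_neg(engine, False), starts, bounds_null, maxiter)

    bounds_alt = (
        [_KAPPA_BOUNDS, prop_bounds, shape_bounds, shape_bounds, (1.0, 30.0)]
        + [_BL_BOUNDS] * nb
    )
    warm = np.concatenate((res_null.x[:4], [1.0 + 1e-3], res_null.x[4:]))
    starts_alt = [warm]
    if restarts > 1:
        hot = warm.copy()
        hot[1] = min(hot[1] + 0.05, 1 - 1e-4)
        hot[4] = 3.0
        starts_alt.append(hot)
    res_alt = _multi_start(_m8_like_neg(engine, True), starts_alt, bounds_alt, maxiter)

    # re-fit the null from the alternative's projection (omega_s -> 1): the
    # models are nested, so an underfitted null would inflate the LRT
    proj = np.concatenate((res_alt.x[:4], res_alt.x[5:]))
    res_null2 = _minimize(_m8_like_neg(engine, False), proj, bounds_null, maxiter)
    if res_null2.fun < res_null.fun:
        res_null = res_null2

    lnl_m8, lnl_m8a = -res_alt.fun, -res_null.fun
    stat = max(0.0, 2.0 * (lnl_m8 - lnl_m8a))
    p = float(stats.chi2.sf(stat, df=1))
    return M8PairFit(
        lnL_m8=float(lnl_m8),
        lnL_m8a=float(lnl_m8a),
        p_value=p,
        m8_params={
            "kappa": float(res_alt.x[0]),
            "p0": float(res_alt.x[1]),
            "p": float(res_alt.x[2]),
            "q": float(res_alt.x[3]),
            "omega_s": float(res_alt.x[4]),
            "branch_lengths": res_alt.x[5:].copy(),
        },
        m8a_params={
            "kappa": float(res_null.x[0]),
            "p0": float(res_null.x[1]),
            "p": float(res_null.x[2]),
            "q": float(res_null.x[3]),
            "branch_lengths": res_null.x[4:].copy(),
        },
    )


@dataclass
class BranchSiteFit:
    foreground_branch: str
    lnL_alt: float
    lnL_null: float
    p_value: float
    omega2: float
    site_posteriors: np.ndarray  # P(positive-selection class) per alignment site
    selected_sites: list[int]


def _branch_site_neg(engine, fg_edge: int, free_omega2: bool):
    def neg(x):
        kappa, s, r, omega0 = x[0], x[1], x[2], x[3]
        omega2 = x[4] if free_omega2 else 1.0
        bl = x[5:] if free_omega2 else x[4:]
        classes = branch_site_classes(s * r, s * (1.0 - r), omega0, omega2)
        return -engine.log_likelihood(kappa, classes, bl, foreground_edge=fg_edge)

    return neg


def fit_branch_site(
    alignment: CodonAlignment,
    tree: dendropy.Tree,
    foreground_branch: str,
    pi: Optional[np.ndarray] = None,
    restarts: int = 2,
    maxiter: int = 300,
    posterior_threshold: float = 0.95,
) -> BranchSiteFit:
    """Branch-site model A vs its ``omega_2 = 1`` null on one branch.

    Site posteriors for the positive-selection classes (2a+2b) come from a
    naive empirical Bayes evaluation at the alternative-model optimum.
    """
    engine = _Engine(alignment, tree, pi=pi)
    fg_edge = engine.ti.edge_index_for(foreground_branch)
    nb = engine.ti.n_edges
    bl0 = np.clip(engine.ti.init_lengths, 1e-4, 10.0)
    sr_bounds = (1e-3, 1.0 - 1e-3)
    bounds_null = [_KAPPA_BOUNDS, sr_bounds, sr_bounds, (1e-4, 1.0)] + [_BL_BOUNDS] * nb
    x0 = np.concatenate(([2.0, 0.85, 0.7, 0.2], bl0))
    starts = [x0] + [_jitter(x0, bounds_null, seed=3000 + i) for i in range(1, restarts)]
    res_null = _multi_start(_branch_site_neg(engine, fg_edge, False), starts, bounds_null, maxiter)

    bounds_alt = [_KAPPA_BOUNDS, sr_bounds, sr_bounds, (1e-4, 1.0), (1.0, 30.0)] + [_BL_BOUNDS] * nb
    warm = np.concatenate((res_null.x[:4], [1.0 + 1e-3], res_null.x[4:]))
    starts_alt = [warm]
    if restarts > 1:
        hot = warm.copy()
        hot[4] = 4.0
        starts_alt.append(hot)
    res_alt = _multi_start(_branch_site_neg(engine, fg_edge, True), starts_alt, bounds_alt, maxiter)

    lnl_alt, lnl_null = -res_alt.fun, -res_null.fun
    stat = max(0.0, 2.0 * (lnl_alt - lnl_null))
    p = float(stats.chi2.sf(stat, df=1))

    kappa, s, r, omega0, omega2 = res_alt.x[:5]
    classes = branch_site_classes(s * r, s * (1.0 - r), omega0, omega2)
    class_site, mix = engine.site_log_likelihoods(
        kappa, classes, res_alt.x[5:], foreground_edge=fg_edge
    )
    with np.errstate(under="ignore"):
        post = np.exp(
            special.logsumexp(
                class_site[2:] + np.log(classes.weights[2:, None]), axis=0
            )
            - mix
        )
    site_post = post[engine.site_to_pattern]
    selected = [int(i) for i in np.flatnonzero(site_post > posterior_threshold)]
    return BranchSiteFit(
        foreground_branch=foreground_branch,
        lnL_alt=float(lnl_alt),
        lnL_null=float(lnl_null),
        p_value=p,
        omega2=float(omega2),
        site_posteriors=site_post,
        selected_sites=selected,
    )


# ---------------------------------------------------------------------------
# The gated cascade

@dataclass
class BranchTestRecord:
    branch: str
    p_value: float
    q_value: float
    omega2: float
    selected_sites: list[int]


@dataclass
class CladeResult:
    """One clade's row of the selection screen."""

    clade: str
    n_sequences: int
    omega_m0: float
    kappa: float
    gate: float
    m8_tested: bool
    p_m8: Optional[float] = None
    skip_reason: Optional[str] = None
    branch_tests: list[BranchTestRecord] = field(default_factory=list)
    positively_selected: list[str] = field(default_factory=list)

    @property
    def branch_stage_ran(self) -> bool:
        return bool(self.branch_tests)


@dataclass
class CascadeReport:
    clades: dict[str, CladeResult]

    def to_rows(self) -> list[dict]:
        rows = []
        for name, c in sorted(self.clades.items()):
            rows.append(
                {
                    "clade": name,
                    "n_sequences": c.n_sequences,
                    "omega_m0": round(c.omega_m0, 5),
                    "p_m8_vs_m8a": ("/" if not c.m8_tested else round(c.p_m8, 6)),
                    "branch_site": (
                        ",".join(c.positively_selected)
                        if c.branch_stage_ran and c.positively_selected
                        else ("NS" if c.branch_stage_ran else "/")
                    ),
                }
            )
        return rows


def run_cascade(
    clade_alignments: Mapping[str, CodonAlignment],
    clade_trees: Mapping[str, dendropy.Tree],
    omega_gate: float = 0.3,
    alpha: float = 0.05,
    q_threshold: float = 0.05,
    restarts: int = 2,
    maxiter: int = 300,
) -> CascadeReport:
    """Run the gated selection screen over a set of clades.

    Gate semantics: the M8-vs-M8a comparison runs only when the clade's M0
    omega exceeds ``omega_gate``; branch-site tests run only when that
    comparison is significant at ``alpha``; q-values are computed across the
    terminal-branch tests within each clade, and branches significant at
    ``q_threshold`` are reported with their high-posterior sites.
    """
    clades: dict[str, CladeResult] = {}
    for name in sorted(clade_alignments):
        aln = clade_alignments[name]
        tree = clade_trees[name]
        m0 = fit_m0(aln, tree, restarts=restarts, maxiter=maxiter)
        result = CladeResult(
            clade=name,
            n_sequences=aln.n_taxa,
            omega_m0=m0.omega,
            kappa=m0.kappa,
            gate=omega_gate,
            m8_tested=m0.omega > omega_gate,
        )
        if not result.m8_tested:
            result.skip_reason = (
                f"omega_M0={m0.omega:.5f} <= gate {omega_gate}: site test skipped"
            )
            clades[name] = result
            continue
        pair = fit_m8_pair(aln, tree, restarts=restarts, maxiter=maxiter)
        result.p_m8 = pair.p_value
        if pair.p_value >= alpha:
            result.skip_reason = (
                f"M8 vs M8a p={pair.p_value:.4f} >= alpha {alpha}: branch stage skipped"
            )
            clades[name] = result
            continue
        terminal = sorted(aln.taxa)
        fits = [
            fit_branch_site(aln, tree, leaf, restarts=restarts, maxiter=maxiter)
            for leaf in terminal
        ]
        qs = compute_qvalues([f.p_value for f in fits])
        for f, q in zip(fits, qs):
            rec = BranchTestRecord(
                branch=f.foreground_branch,
                p_value=f.p_value,
                q_value=float(q),
                omega2=f.omega2,
                selected_sites=f.selected_sites,
            )
            result.branch_tests.append(rec)
            if rec.q_value < q_threshold:
                result.positively_selected.append(rec.branch)
        clades[name] = result
    return CascadeReport(clades=clades)
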