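"""Genetic-code utilities and the GY94 codon substitution model.

The model is the Goldman–Yang form used by codeml: for codons *i*, *j*
differing at a single nucleotide,

    q_ij  ∝  pi_j · kappa^[transition] · omega^[nonsynonymous]

with all multi-nucleotide changes instantaneous-rate zero.  ``kappa`` is the
transition/transversion rate ratio, ``omega`` the nonsynonymous/synonymous
rate ratio (dN/dS), and ``pi`` the codon equilibrium frequencies (F3x4 by
default).  The generator is scaled so the expected number of substitutions
per codon site is one at equilibrium.
"""

from __future__ import annotations

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

NUCS = "ACGT"
COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: the 61 sense codons of the standard code, in lexicographic order
SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c in (a + b + d for a in NUCS for b in NUCS for d in NUCS)
           if c not in standard_dna_table.stop_codons)
)
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}
STOP_CODONS = frozenset(standard_dna_table.stop_codons)
CODON_TO_AA: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in STOP_CODONS:
    CODON_TO_AA[_stop] = "*"

START_CODON = "ATG"

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def translate(seq: str) -> str:
    """Translate a nucleotide sequence codon-by-codon (standard code).

    Trailing partial codons are dropped; any codon containing a character
    outside ``ACGT`` (e.g. assembly ``N``) translates to ``X``.
    """
    if not seq:
        raise ValueError("cannot translate an empty sequence")
    seq = seq.upper()
    out = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        out.append(CODON_TO_AA.get(seq[i : i + 3], "X"))
    return "".join(out)


def six_frame_translate(seq: str) -> dict[int, str]:
    """All six reading-frame translations, keyed +1..+3 / -1..-3.

    Frame +k starts at 0-based offset k-1 of the forward strand; frame -k at
    offset k-1 of the reverse complement.
    """
    if not seq:
        raise ValueError("cannot translate an empty sequence")
    rc = reverse_complement(seq)
    frames: dict[int, str] = {}
    for k in (1, 2, 3):
        fwd, rev = seq[k - 1 :], rc[k - 1 :]
        frames[k] = translate(fwd) if len(fwd) >= 3 else ""
        frames[-k] = translate(rev) if len(rev) >= 3 else ""
    return frames


# ---------------------------------------------------------------------------
# GY94

def _single_nt_change(ci: str, cj: str) -> tuple[int, str, str] | None:
    """Position and nucleotides of the single difference, or None."""
    diff = [(p, a, b) for p, (a, b) in enumerate(zip(ci, cj)) if a != b]
    return diff[0] if len(diff) == 1 else None


def _build_exchange_masks() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Precompute 61x61 masks: single-change indicator x target-nt column,
    transition indicator, nonsynonymous indicator."""
    n = len(SENSE_CODONS)
    allowed = np.zeros((n, n), dtype=bool)
    transition = np.zeros((n, n), dtype=bool)
    nonsyn = np.zeros((n, n), dtype=bool)
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            d = _single_nt_change(ci, cj)
            if d is None:
                continue
            allowed[i, j] = True
            transition[i, j] = (d[1], d[2]) in _TRANSITIONS
            nonsyn[i, j] = CODON_TO_AA[ci] != CODON_TO_AA[cj]
    return allowed, transition, nonsyn


_ALLOWED, _TRANSITION, _NONSYN = _build_exchange_masks()


def f3x4_frequencies(codon_columns: np.ndarray) -> np.ndarray:
    """F3x4 codon frequencies from codon-index columns (gaps coded as -1).

    Position-specific nucleotide frequencies are estimated from the observed
    codons, multiplied per codon, restricted to the 61 sense codons and
    renormalised.
    """
    counts = np.zeros((3, 4))
    flat = codon_columns.ravel()
    for ci in flat[flat >= 0]:
        codon = SENSE_CODONS[ci]
        for pos, nt in enumerate(codon):
            counts[pos, NUCS.index(nt)] += 1
    if counts.sum() == 0:
        raise ValueError("no codons observed; cannot estimate frequencies")
    counts += 0.5  # small prior keeps unseen nucleotides feasible
    pos_freq = counts / counts.sum(axis=1, keepdims=True)
    pi = np.array(
        [
            pos_freq[0, NUCS.index(c[0])]
            * pos_freq[1, NUCS.index(c[1])]
            * pos_freq[2, NUCS.index(c[2])]
            for c in SENSE_CODONS
        ]
    )
    return pi / pi.sum()


def uniform_frequencies() -> np.ndarray:
    return np.full(len(SENSE_CODONS), 1.0 / len(SENSE_CODONS))


def gy94_rate_matrix(
    kappa: float, omega: float, pi: np.ndarray, scale: bool = True
) -> np.ndarray:
    """GY94 generator Q for one omega class.

    Rows sum to zero.  With ``scale=True`` the matrix is normalised so that
    the expected substitution rate at equilibrium, ``-sum_i pi_i q_ii``,
    equals one.  For site-class mixtures pass ``scale=False`` and apply a
    shared mixture-level scale (see :func:`scaled_class_matrices`).
    """
    if kappa <= 0 or omega < 0:
        raise ValueError("require kappa > 0 and omega >= 0")
    q = np.where(_ALLOWED, pi[None, :], 0.0)
    q = q * np.where(_TRANSITION, kappa, 1.0) * np.where(_NONSYN, omega, 1.0)
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    if scale:
        rate = -np.dot(pi, np.diag(q))
        if rate > 0:
            q /= rate
    return q


def scaled_class_matrices(
    kappa: float,
    omegas: np.ndarray,
    weights: np.ndarray,
    pi: np.ndarray,
) -> list[np.ndarray]:
    """Per-class GY94 generators under a common mixture-average scaling.

    All classes share one scale factor so that the weight-averaged expected
    substitution rate is one substitution per codon site (codeml behaviour).
    """
    qs = [gy94_rate_matrix(kappa, w, pi, scale=False) for w in omegas]
    mean_rate = sum(
        wgt * (-np.dot(pi, np.diag(q))) for wgt, q in zip(weights, qs)
    )
    if mean_rate <= 0:
        mean_rate = 1.0
    return [q / mean_rate for q in qs]


def transition_probabilities(q: np.ndarray, pi: np.ndarray, t: float) -> np.ndarray:
    """P(t) = exp(Qt) for a reversible generator via symmetric eigensolve."""
    d_sqrt = np.sqrt(pi)
    s = (q * d_sqrt[:, None]) / d_sqrt[None, :]
    s = (s + s.T) / 2.0  # enforce symmetry against round-off
    eigval, eigvec = np.linalg.eigh(s)
    p = (eigvec * np.exp(eigval * t)) @ eigvec.T
    p = (p / d_sqrt[:, None]) * d_sqrt[None, :]
    np.clip(p, 0.0, None, out=p)
    p /= p.sum(axis=1, keepdims=True)
    return p


class EigenQ:
    """Cached eigendecomposition of a reversible Q for repeated P(t) calls."""

    def __init__(self, q: np.ndarray, pi: np.ndarray):
        d_sqrt = np.sqrt(pi)
        s = (q * d_sqrt[:, None]) / d_sqrt[None, :]
        s = (s + s.T) / 2.0
        self.eigval, self.eigvec = np.linalg.eigh(s)
        self._left = self.eigvec / d_sqrt[:, None]
        self._right = (self.eigvec * d_sqrt[:, None]).T

    def p(self, t: float) -> np.ndarray:
        p = (self._left * np.exp(self.eigval * t)) @ self._right
        np.clip(p, 0.0, None, out=p)
        rowsum = p.sum(axis=1, keepdims=True)
        rowsum[rowsum == 0] = 1.0
        return p / rowsum
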