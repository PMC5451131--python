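"""Pedigree and genomic relationship matrices and the single-step H inverse.

The numerator relationship matrix A comes from the tabular method; its
sparse inverse from Henderson's rules with inbreeding coefficients computed
by the Meuwissen-Luo ancestor-traversal algorithm (no dense A needed). The
genomic matrix G follows VanRaden's first method with observed allele
frequencies,

    G = M M' / (2 * sum_i p_i (1 - p_i)),    M = Z - 2p,

optionally weighted per marker (G_D = M D M' / 2*sum p q) and blended with
the pedigree block A22 as (1 - w) G + w A22 (default w = 0.05) to guarantee
invertibility. The single-step inverse is

    H^-1 = A^-1 + [[0, 0], [0, G_b^-1 - A22^-1]]

with the genomic block indexed by the genotyped animals' pedigree positions
(tau = omega = 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .datatypes import GenotypePanel, Pedigree


def numerator_relationship(pedigree: Pedigree) -> tuple[np.ndarray, np.ndarray]:
    """Dense A by the tabular method plus per-animal inbreeding F.

    a_ij = 0.5 (a_j,sire(i) + a_j,dam(i)); diag = 1 + 0.5 a_sire,dam.
    Quadratic in pedigree size; intended for desk-scale pedigrees.
    """
    sires, dams = pedigree.parent_indices()
    n = pedigree.n_animals
    a = np.zeros((n, n))
    for i in range(n):
        s, d = sires[i], dams[i]
        if s >= 0 and d >= 0:
            a[i, :i] = 0.5 * (a[s, :i] + a[d, :i])
            a[i, i] = 1.0 + 0.5 * a[s, d]
        elif s >= 0 or d >= 0:
            known = s if s >= 0 else d
            a[i, :i] = 0.5 * a[known, :i]
            a[i, i] = 1.0
        else:
            a[i, i] = 1.0
        a[:i, i] = a[i, :i]
    return a, np.diag(a) - 1.0


def inbreeding(pedigree: Pedigree) -> np.ndarray:
    """Meuwissen-Luo inbreeding coefficients.

    For each animal, a_ii = sum_j L_ij^2 d_j is accumulated by walking its
    ancestor set from youngest to oldest, where d_j is the Mendelian
    sampling variance of ancestor j; F = a_ii - 1. Linear memory.
    """
    sires, dams = pedigree.parent_indices()
    n = pedigree.n_animals
    f = np.zeros(n)
    d = np.zeros(n)  # Mendelian sampling variances
    for i in range(n):
        s, dd = sires[i], dams[i]
        fs = f[s] if s >= 0 else -1.0
        fd = f[dd] if dd >= 0 else -1.0
        d[i] = 0.5 - 0.25 * (fs + fd)
        if s < 0 or dd < 0:
            f[i] = 0.0
            continue
        coeff: dict[int, float] = {i: 1.0}
        aii = 0.0
        while coeff:
            j = max(coeff)
            cj = coeff.pop(j)
            aii += cj * cj * d[j]
            for p in (sires[j], dams[j]):
                if p >= 0:
                    coeff[p] = coeff.get(p, 0.0) + 0.5 * cj
        f[i] = aii - 1.0
    return f


def a_inverse(pedigree: Pedigree) -> sparse.csr_matrix:
    """Sparse A^-1 by Henderson's rules with Meuwissen-Luo inbreeding."""
    sires, dams = pedigree.parent_indices()
    f = inbreeding(pedigree)
    n = pedigree.n_animals
    rows, cols, vals = [], [], []

    def add(i, j, v):
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for i in range(n):
        s, d = sires[i], dams[i]
        fs = f[s] if s >= 0 else -1.0
        fd = f[d] if d >= 0 else -1.0
        b = 1.0 / (0.5 - 0.25 * (fs + fd))
        add(i, i, b)
        for p in (s, d):
            if p >= 0:
                add(i, p, -0.5 * b)
                add(p, i, -0.5 * b)
                for q in (s, d):
                    if q >= 0:
                        add(p, q, 0.25 * b)
    return sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()


def genomic_relationship(panel: GenotypePanel,
                         weights: np.ndarray | None = None,
                         blend_weight: float = 0.05,
                         a22: np.ndarray | None = None,
                         tune_to_a22: bool = False,
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """VanRaden G over the panel's animals, blended toward A22.

    Missing dosages are imputed with the marker mean 2 p_i; monomorphic
    markers are excluded (their centered column is all-zero and contributes
    nothing to the denominator). Returns (G_blended, p, used_markers).
    ``tune_to_a22`` applies the two-coefficient adjustment matching mean
    diagonal and mean off-diagonal of G to A22 before blending (off by
    default). With ``blend_weight`` > 0 an ``a22`` must be supplied.
    """
    d = panel.dosages.T.astype(float).copy()  # animals x markers
    p = np.nanmean(d, axis=0) / 2.0
    poly = (p > 0.0) & (p < 1.0)
    if not poly.all():
        warnings.warn(f"excluding {int((~poly).sum())} monomorphic markers from G")
    d = d[:, poly]
    p_used = p[poly]
    nanmask = np.isnan(d)
    if nanmask.any():
        d[nanmask] = np.broadcast_to(2.0 * p_used, d.shape)[nanmask]
    m = d - 2.0 * p_used
    het = 2.0 * np.sum(p_used * (1.0 - p_used))
    if weights is not None:
        w = np.asarray(weights, dtype=float)[poly]
        g = (m * w) @ m.T / het
    else:
        g = m @ m.T / het
    if blend_weight > 0.0:
        if a22 is None:
            raise ValueError("blending requires the pedigree block A22")
        if tune_to_a22:
            g = _tune(g, a22)
        g = (1.0 - blend_weight) * g + blend_weight * a22
    elif tune_to_a22:
        if a22 is None:
            raise ValueError("tuning requires A22")
        g = _tune(g, a22)
    return g, p, np.flatnonzero(poly)


def _tune(g: np.ndarray, a22: np.ndarray) -> np.ndarray:
    """Two-coefficient rescaling so mean(diag) and mean(offdiag) of G match A22."""
    n = g.shape[0]
    off = ~np.eye(n, dtype=bool)
    gd, go = np.diag(g).mean(), g[off].mean()
    ad, ao = np.diag(a22).mean(), a22[off].mean()
    beta = (ad - ao) / (gd - go)
    alpha = ao - beta * go
    return alpha + beta * g


@dataclass
class HInverseParts:
    """H^-1 in its natural two-part form.

    ``a_inv`` is sparse over all pedigree animals; ``delta`` is the dense
    genomic correction G_blended^-1 - A22^-1 over genotyped animals;
    ``genotyped_idx`` maps the delta block's rows to pedigree positions.
    """

    a_inv: sparse.csr_matrix
    delta: np.ndarray
    genotyped_idx: np.ndarray

    @property
    def n_animals(self) -> int:
        return self.a_inv.shape[0]

    def to_sparse(self) -> sparse.csr_matrix:
        """Materialize H^-1 (sparse plus the embedded dense block)."""
        h = self.a_inv.tolil(copy=True)
        idx = self.genotyped_idx
        if len(idx):
            h[np.ix_(idx, idx)] = h[np.ix_(idx, idx)].toarray() + self.delta
        return h.tocsr()

    def matvec(self, x: np.ndarray) -> np.ndarray:
        y = self.a_inv @ x
        if len(self.genotyped_idx):
            y[self.genotyped_idx] += self.delta @ x[self.genotyped_idx]
        return y

    def quadratic(self, x: np.ndarray) -> float:
        """x' H^-1 x."""
        return float(x @ self.matvec(x))


def h_inverse(a_inv: sparse.csr_matrix, a22: np.ndarray,
              g_blended: np.ndarray, genotyped_idx: np.ndarray,
              ) -> HInverseParts:
    """Assemble the single-step inverse from its ingredients."""
    genotyped_idx = np.asarray(genotyped_idx, dtype=np.int64)
    if len(genotyped_idx) == 0:
        return HInverseParts(a_inv.tocsr(), np.zeros((0, 0)), genotyped_idx)
    if g_blended.shape[0] != len(genotyped_idx) or a22.shape != g_blended.shape:
        raise ValueError("genomic block dimensions must match genotyped count")
    try:
        g_inv = np.linalg.inv(g_blended)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "G_blended is singular; increase blend_weight toward A22") from exc
    a22_inv = np.linalg.inv(a22)
    return HInverseParts(a_inv.tocsr(), g_inv - a22_inv, genotyped_idx)


@dataclass
class SingleStepMatrices:
    """Everything the single-step evaluation and back-solving need."""

    h_inv: HInverseParts
    g_blended: np.ndarray
    a22: np.ndarray
    p: np.ndarray            # allele frequencies over all panel markers
    used_markers: np.ndarray  # indices of polymorphic markers used in G

    def __iter__(self):  # backwards-friendly (parts, p, used) unpacking
        return iter((self.h_inv, self.p, self.used_markers))


def build_h_inverse(pedigree: Pedigree, panel: GenotypePanel,
                    genotyped_ids: list[str], blend_weight: float = 0.05,
                    weights: np.ndarray | None = None,
                    tune_to_a22: bool = False) -> SingleStepMatrices:
    """Convenience pipeline: A^-1, A22, (weighted) G, blend, assemble.

    ``panel`` must already be restricted to ``genotyped_ids`` (same order).
    """
    if list(panel.animal_ids) != list(genotyped_ids):
        raise ValueError("panel animals must equal genotyped_ids in order")
    a_inv = a_inverse(pedigree)
    idx = pedigree.indices(genotyped_ids)
    a_full, _ = numerator_relationship(pedigree)
    a22 = a_full[np.ix_(idx, idx)]
    g, p, used = genomic_relationship(panel, weights=weights,
                                      blend_weight=blend_weight, a22=a22,
                                      tune_to_a22=tune_to_a22)
    return SingleStepMatrices(h_inverse(a_inv, a22, g, idx), g, a22, p, used)
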