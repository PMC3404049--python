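"""Character compatibility analysis of binary band matrices.

Two binary characters (loci) are *incompatible* when all four state
combinations 0/0, 1/0, 0/1 and 1/1 co-occur among the genotypes — the
four-gamete condition.  Under infinite-sites mutation on a genealogy no
pair can be incompatible, so incompatibility is the signature of sexual
recombination (or recurrent mutation).  The matrix incompatibility count
(MIC) sums the condition over all unordered locus pairs; jackknifing one
genotype at a time ranks genotypes as likely recombinants, and deleting
the top-ranked genotype repeatedly until MIC reaches zero measures how
much of the genotype pool owes its existence to recombination.

All operations work on the *distinct-genotype* matrix: duplicate band
vectors (putative clones) are collapsed first, so the deletion trajectory
counts genotypes, not individuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix import MISSING, GenotypeTable

__all__ = [
    "IncompatibilityResult",
    "DeletionTrajectory",
    "pair_incompatible",
    "matrix_incompatibility",
    "jackknife_contributions",
    "successive_deletion",
    "perfect_phylogeny_check",
]


@dataclass
class IncompatibilityResult:
    """Pairwise incompatibilities of one genotype matrix.

    ``mic`` is the number of incompatible unordered locus pairs;
    ``contributions`` (when filled) maps each genotype ID to
    ``MIC(all) - MIC(all minus that genotype)``.
    """

    incompatible_pairs: set[tuple[str, str]]
    mic: int
    contributions: dict[str, int] = field(default_factory=dict)


@dataclass
class DeletionTrajectory:
    """Successive-deletion record: which genotypes were removed, and the
    MIC of the surviving matrix after each removal (index 0 = no
    deletions)."""

    deleted_order: list[str]
    mic_after: list[int]
    n_genotypes_initial: int
    tie_steps: list[int] = field(default_factory=list)

    @property
    def n_deleted_to_zero(self) -> int:
        return len(self.deleted_order)

    @property
    def fraction_deleted(self) -> float:
        if self.n_genotypes_initial == 0:
            return 0.0
        return self.n_deleted_to_zero / self.n_genotypes_initial


def _as_matrix(genotypes) -> tuple[np.ndarray, list[str], list[str]]:
    """Accept a GenotypeTable or a bare 2-D array of band states."""
    if isinstance(genotypes, GenotypeTable):
        locus_ids = genotypes.locus_ids or [str(j) for j in range(genotypes.vectors.shape[1])]
        return genotypes.vectors, list(genotypes.genotype_ids), locus_ids
    M = np.asarray(genotypes, dtype=np.int8)
    if M.ndim != 2:
        raise ValueError("genotype matrix must be 2-D")
    return M, [f"G{i + 1:02d}" for i in range(M.shape[0])], [str(j) for j in range(M.shape[1])]


def pair_incompatible(col_a, col_b) -> bool:
    """Four-gamete test for two band columns.

    Rows where either column is missing are ignored (pairwise-complete
    deletion); with no jointly scored row the pair counts as compatible.
    """
    a = np.asarray(col_a, dtype=np.int8)
    b = np.asarray(col_b, dtype=np.int8)
    if a.shape != b.shape:
        raise ValueError("columns must have equal length")
    ok = (a != MISSING) & (b != MISSING)
    a, b = a[ok], b[ok]
    combos = {(int(x), int(y)) for x, y in zip(a, b)}
    return len(combos) == 4


def _combo_counts(M: np.ndarray):
    """Per-locus-pair counts of the four state combinations.

    Returns the four L x L matrices C11, C10, C01, C00 where e.g.
    ``C10[i, j]`` counts genotypes scored 1 at locus i and 0 at locus j.
    Missing entries contribute to no combination.
    """
    P = (M == 1).astype(np.int32)
    A = (M == 0).astype(np.int32)
    return P.T @ P, P.T @ A, A.T @ P, A.T @ A


def _mic_from_counts(C11, C10, C01, C00) -> np.ndarray:
    """Boolean L x L matrix of incompatible pairs (upper triangle valid)."""
    return (C11 > 0) & (C10 > 0) & (C01 > 0) & (C00 > 0)


def matrix_incompatibility(genotypes) -> IncompatibilityResult:
    """MIC and the set of incompatible locus pairs of a genotype matrix.

    Degenerate inputs (fewer than two genotypes or loci) have MIC = 0.
    """
    M, _, locus_ids = _as_matrix(genotypes)
    if M.shape[0] < 2 or M.shape[1] < 2:
        return IncompatibilityResult(set(), 0)
    inc = _mic_from_counts(*_combo_counts(M))
    iu = np.triu_indices(M.shape[1], k=1)
    hits = inc[iu]
    pairs = {
        (locus_ids[i], locus_ids[j])
        for i, j in zip(iu[0][hits], iu[1][hits])
    }
    return IncompatibilityResult(pairs, int(hits.sum()))


def jackknife_contributions(genotypes) -> IncompatibilityResult:
    """Leave-one-out MIC differences for every genotype.

    contribution(g) = MIC(full matrix) - MIC(matrix without g).  Removing
    one genotype only subtracts its own outer-product from the combo
    counts, so each jackknife replicate is evaluated incrementally.
    """
    M, gids, locus_ids = _as_matrix(genotypes)
    res = matrix_incompatibility(genotypes)
    if M.shape[0] == 0:
        return res
    C11, C10, C01, C00 = _combo_counts(M)
    iu = np.triu_indices(M.shape[1], k=1)
    P = (M == 1).astype(np.int32)
    A = (M == 0).astype(np.int32)
    contributions = {}
    for g, gid in enumerate(gids):
        p, a = P[g], A[g]
        inc = _mic_from_counts(
            C11 - np.outer(p, p),
            C10 - np.outer(p, a),
            C01 - np.outer(a, p),
            C00 - np.outer(a, a),
        )
        contributions[gid] = res.mic - int(inc[iu].sum())
    res.contributions = contributions
    return res


def successive_deletion(genotypes) -> DeletionTrajectory:
    """Delete the highest-contributing genotype until MIC reaches zero.

    Contributions are re-ranked on the surviving matrix after every
    deletion; ties on the maximal contribution are broken toward the
    genotype appearing first (smallest genotype ID), which makes the
    trajectory deterministic.  Steps at which a tie occurred are recorded
    in ``tie_steps``.
    """
    M, gids, locus_ids = _as_matrix(genotypes)
    n0 = M.shape[0]
    deleted: list[str] = []
    ties: list[int] = []
    mic_after = [matrix_incompatibility(M).mic]
    while mic_after[-1] > 0:
        table = GenotypeTable(gids, M, np.ones(len(gids), dtype=int),
                              [[g] for g in gids], locus_ids)
        contr = jackknife_contributions(table).contributions
        best = max(contr.values())
        argmax = [g for g in gids if contr[g] == best]
        if len(argmax) > 1:
            ties.append(len(deleted))
        victim = argmax[0]
        k = gids.index(victim)
        deleted.append(victim)
        M = np.delete(M, k, axis=0)
        gids = gids[:k] + gids[k + 1:]
        mic_after.append(matrix_incompatibility(M).mic)
    return DeletionTrajectory(deleted, mic_after, n0, ties)


def perfect_phylogeny_check(genotypes) -> bool:
    """Does a complete binary matrix admit a perfect phylogeny?

    Tests whether the genotypes can be placed on a tree on which every
    character changes state exactly once (no homoplasy), with unknown
    ancestral states.  The first genotype is taken as the reference:
    every column is complemented where the reference carries a 1, which
    reduces the question to rooted perfect phylogeny with an all-zero
    ancestor, decided by the radix-sort laminar-containment test
    (columns sorted by 1-count; the matrix is tree-like iff, within each
    column, every 1-row points back to the same previous column).  This
    route never evaluates the four-gamete condition, so it serves as an
    independent oracle for the compatibility machinery.
    """
    M, _, _ = _as_matrix(genotypes)
    if (M == MISSING).any():
        raise ValueError("perfect_phylogeny_check requires a complete matrix")
    n, L = M.shape
    if n <= 1 or L == 0:
        return True
    X = (M ^ M[0]).astype(np.int8)  # reference genotype becomes all-zero root
    order = np.argsort(-X.sum(axis=0), kind="stable")
    X = X[:, order]
    # Lmat[i, j] = 1-based index of the rightmost column k < j with X[i, k] = 1
    Lmat = np.zeros((n, L), dtype=np.int64)
    last = np.zeros(n, dtype=np.int64)
    for j in range(L):
        Lmat[:, j] = last
        ones = X[:, j] == 1
        last[ones] = j + 1
    for j in range(L):
        ones = X[:, j] == 1
        if ones.any():
            vals = Lmat[ones, j]
            if (vals != vals[0]).any():
                return False
    return True
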