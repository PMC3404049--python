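"""Band-matrix I/O and multilocus-genotype identification.

Dominant markers (ISSR, AFLP, RAPD) are scored as band presence (1) or
absence (0) per individual per locus; a cell may also be missing.  This
module reads and writes the delimited-text matrix format, restricts a
matrix to one population, drops unscorable loci, and collapses individuals
that share a band vector into multilocus genotypes — the unit of every
downstream analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Internal sentinel for a missing band call (int8 storage).
MISSING: int = -1

__all__ = [
    "MISSING",
    "MarkerMatrix",
    "GenotypeTable",
    "read_matrix",
    "write_matrix",
    "filter_population_loci",
    "identify_genotypes",
    "write_genotype_table",
]


@dataclass
class MarkerMatrix:
    """An individuals x loci band matrix with population labels.

    Parameters
    ----------
    bands
        ``int8`` array of shape ``(n_individuals, n_loci)`` with entries
        0 (band absent), 1 (band present) or :data:`MISSING`.
    individual_ids
        Unique individual labels, one per row.
    populations
        Population label of each individual (parallel to rows).
    locus_ids
        Unique locus labels, one per column.
    """

    bands: np.ndarray
    individual_ids: list[str]
    populations: list[str]
    locus_ids: list[str]

    def __post_init__(self) -> None:
        self.bands = np.asarray(self.bands, dtype=np.int8)
        if self.bands.ndim != 2:
            raise ValueError("bands must be a 2-D array")
        n, L = self.bands.shape
        if len(self.individual_ids) != n or len(self.populations) != n:
            raise ValueError("individual_ids/populations length must match rows")
        if len(self.locus_ids) != L:
            raise ValueError("locus_ids length must match columns")
        if len(set(self.individual_ids)) != n:
            raise ValueError("duplicate individual IDs")
        if len(set(self.locus_ids)) != L:
            raise ValueError("duplicate locus IDs")
        bad = ~np.isin(self.bands, (0, 1, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid band value {int(self.bands[i, j])} at individual "
                f"{self.individual_ids[i]!r}, locus {self.locus_ids[j]!r}"
            )

    # -- basic geometry -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.bands.shape[0]

    @property
    def n_loci(self) -> int:
        return self.bands.shape[1]

    @property
    def population_of(self) -> dict[str, str]:
        """Map from individual ID to population label."""
        return dict(zip(self.individual_ids, self.populations))

    @property
    def population_labels(self) -> list[str]:
        """Distinct population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p)
        return list(seen)

    # -- conversion ------------------------------------------------------
    def to_frame(self, missing_code: str = "?") -> pd.DataFrame:
        """Render as a DataFrame in the on-disk layout."""
        body = self.bands.astype(object)
        body[self.bands == MISSING] = missing_code
        df = pd.DataFrame(body, columns=self.locus_ids)
        df.insert(0, "population", self.populations)
        df.insert(0, "individual", self.individual_ids)
        return df

    def subset_population(self, pop: str) -> "MarkerMatrix":
        """Rows belonging to one population (loci untouched)."""
        mask = [p == pop for p in self.populations]
        if not any(mask):
            raise ValueError(f"population {pop!r} has no individuals")
        idx = np.flatnonzero(mask)
        return MarkerMatrix(
            self.bands[idx],
            [self.individual_ids[i] for i in idx],
            [self.populations[i] for i in idx],
            list(self.locus_ids),
        )


@dataclass
class GenotypeTable:
    """Distinct multilocus genotypes of one population.

    ``vectors`` holds one band vector per distinct genotype over the
    retained loci; ``members`` maps each genotype to the individuals
    carrying it.  Two individuals share a genotype only when their band
    vectors match exactly, with a missing call treated as a state of its
    own — a conservative rule that never chains non-identical putative
    clones together.
    """

    genotype_ids: list[str]
    vectors: np.ndarray  # (n_genotypes, n_loci) int8
    multiplicity: np.ndarray  # (n_genotypes,) int
    members: list[list[str]]
    locus_ids: list[str] = field(default_factory=list)

    @property
    def n_genotypes(self) -> int:
        return len(self.genotype_ids)

    @property
    def n_individuals(self) -> int:
        return int(self.multiplicity.sum())

    @property
    def n_found_once(self) -> int:
        """Genotypes carried by exactly one individual."""
        return int((self.multiplicity == 1).sum())


def read_matrix(path, missing_code: str = "?", sep: str | None = None) -> MarkerMatrix:
    """Read a band matrix from delimited text.

    Layout: header row, first two columns ``individual`` and
    ``population``, then one column per locus with values 0, 1 or
    *missing_code* (``NA`` is always accepted as missing too).  The
    delimiter is sniffed (tab or comma) unless *sep* is given.
    """
    df = pd.read_csv(path, sep=sep, engine="python", dtype=str,
                     keep_default_na=False)
    if df.shape[1] < 3:
        raise ValueError("matrix file needs individual, population and >=1 locus column")
    ind_col, pop_col = df.columns[:2]
    locus_ids = [str(c) for c in df.columns[2:]]
    individual_ids = df[ind_col].astype(str).tolist()
    if len(set(individual_ids)) != len(individual_ids):
        dupes = sorted({i for i in individual_ids if individual_ids.count(i) > 1})
        raise ValueError(f"duplicate individual IDs: {dupes}")
    populations = df[pop_col].astype(str).tolist()

    raw = df.iloc[:, 2:].to_numpy(dtype=object)
    bands = np.empty(raw.shape, dtype=np.int8)
    for (i, j), tok in np.ndenumerate(raw):
        tok = str(tok).strip()
        if tok == "0":
            bands[i, j] = 0
        elif tok == "1":
            bands[i, j] = 1
        elif tok in (missing_code, "NA"):
            bands[i, j] = MISSING
        else:
            raise ValueError(
                f"invalid token {tok!r} at individual {individual_ids[i]!r}, "
                f"locus {locus_ids[j]!r}"
            )
    return MarkerMatrix(bands, individual_ids, populations, locus_ids)


def write_matrix(m: MarkerMatrix, path, missing_code: str = "?", sep: str = "\t") -> None:
    """Write the matrix in the same dialect :func:`read_matrix` accepts."""
    m.to_frame(missing_code).to_csv(path, sep=sep, index=False)


def filter_population_loci(m: MarkerMatrix, pop: str) -> MarkerMatrix:
    """Restrict to one population and drop loci with no scorable entry.

    Only loci in which *every* individual of the population is missing
    are removed; a locus scored in at least one individual is retained.
    """
    sub = m.subset_population(pop)
    scorable = (sub.bands != MISSING).any(axis=0)
    keep = np.flatnonzero(scorable)
    return MarkerMatrix(
        sub.bands[:, keep],
        sub.individual_ids,
        sub.populations,
        [sub.locus_ids[j] for j in keep],
    )


def identify_genotypes(m: MarkerMatrix, pop: str | None = None) -> GenotypeTable:
    """Collapse individuals with identical band vectors into genotypes.

    Missing is a distinct state: individuals match only if they agree at
    every locus, including the pattern of missing calls.  Genotypes are
    numbered in order of first appearance (``G01``, ``G02``, ...).
    """
    sub = m if pop is None else m.subset_population(pop)
    order: dict[tuple, int] = {}
    members: list[list[str]] = []
    for ind, row in zip(sub.individual_ids, sub.bands):
        key = tuple(row.tolist())
        g = order.get(key)
        if g is None:
            order[key] = len(members)
            members.append([ind])
        else:
            members[g].append(ind)
    vectors = np.array([list(k) for k in order], dtype=np.int8)
    if vectors.size == 0:
        vectors = vectors.reshape(0, sub.n_loci)
    mult = np.array([len(ms) for ms in members], dtype=int)
    width = max(2, len(str(len(members))))
    ids = [f"G{i + 1:0{width}d}" for i in range(len(members))]
    return GenotypeTable(ids, vectors, mult, members, list(sub.locus_ids))


def write_genotype_table(t: GenotypeTable, path, sep: str = "\t",
                         missing_code: str = "?") -> None:
    """Write genotypes as TSV: id, multiplicity, members, band vector."""
    vec = t.vectors.astype(object)
    vec[t.vectors == MISSING] = missing_code
    rows = {
        "genotype_id": t.genotype_ids,
        "multiplicity": t.multiplicity,
        "members": [",".join(ms) for ms in t.members],
        "bands": ["".join(str(v) for v in row) for row in vec],
    }
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)
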