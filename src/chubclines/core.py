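"""Core data container for genotype-likelihood data.

The whole pipeline operates on :class:`GLMatrix`: for every individual and
every biallelic SNP a normalized likelihood triple ``(L0, L1, L2)`` giving the
probability of the observed reads under 0, 1 or 2 copies of the alternate
allele. Genotypes are never "called"; downstream models integrate over the
triple. Missing data is the uninformative triple ``(1/3, 1/3, 1/3)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GLMatrix", "FilterReport"]

#: tolerance on the sum-to-one invariant of likelihood triples
_NORM_TOL = 1e-9


@dataclass
class GLMatrix:
    """Individuals x loci x 3 normalized genotype likelihoods.

    Parameters
    ----------
    individuals : array-like of str
        Sample identifiers, length N.
    loci : pandas.DataFrame
        One row per locus with at least columns ``locus_id`` and ``contig``.
        Optional columns ``pos``, ``ref``, ``alt``.
    gl : ndarray, shape (N, L, 3)
        Normalized likelihood triples; each triple sums to 1.
    depth : ndarray of int, shape (N, L), optional
        Read depth per cell; 0 encodes missing data.
    """

    individuals: np.ndarray
    loci: pd.DataFrame
    gl: np.ndarray
    depth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.individuals = np.asarray(self.individuals, dtype=object)
        self.gl = np.asarray(self.gl, dtype=float)
        if self.gl.ndim != 3 or self.gl.shape[2] != 3:
            raise ValueError(f"gl must have shape (N, L, 3), got {self.gl.shape}")
        n, l = self.gl.shape[:2]
        if len(self.individuals) != n:
            raise ValueError("individuals length does not match gl")
        if not isinstance(self.loci, pd.DataFrame):
            self.loci = pd.DataFrame(self.loci)
        if len(self.loci) != l:
            raise ValueError("loci table length does not match gl")
        for col in ("locus_id", "contig"):
            if col not in self.loci.columns:
                raise ValueError(f"loci table missing required column {col!r}")
        self.loci = self.loci.reset_index(drop=True)
        sums = self.gl.sum(axis=2)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("likelihood triples must be normalized to sum 1")
        # renormalize exactly so the 1e-9 invariant holds after round trips
        self.gl = self.gl / sums[:, :, None]
        if self.depth is not None:
            self.depth = np.asarray(self.depth)
            if self.depth.shape != (n, l):
                raise ValueError("depth shape does not match gl")

    # -- basic geometry -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.gl.shape[0]

    @property
    def n_loci(self) -> int:
        return self.gl.shape[1]

    @property
    def locus_ids(self) -> np.ndarray:
        return self.loci["locus_id"].to_numpy()

    @property
    def contigs(self) -> np.ndarray:
        return self.loci["contig"].to_numpy()

    def indices_of(self, ids) -> np.ndarray:
        """Row indices of the given individual ids (order preserved)."""
        lookup = {ind: i for i, ind in enumerate(self.individuals)}
        missing = [x for x in ids if x not in lookup]
        if missing:
            raise KeyError(f"unknown individuals: {missing}")
        return np.array([lookup[x] for x in ids], dtype=int)

    # -- derived channels ------------------------------------------------
    def covered(self) -> np.ndarray:
        """Boolean (N, L) mask of cells carrying read information.

        A cell is covered iff its depth is >= 1; without a depth channel a
        cell counts as covered iff its likelihood triple is non-uniform.
        """
        if self.depth is not None:
            return self.depth >= 1
        return ~np.all(np.abs(self.gl - 1.0 / 3.0) < 1e-9, axis=2)

    def mean_genotype(self) -> np.ndarray:
        """Expected alternate-allele dosage L1 + 2*L2, shape (N, L)."""
        return self.gl[:, :, 1] + 2.0 * self.gl[:, :, 2]

    # -- subsetting -------------------------------------------------------
    def subset(self, individual_mask=None, locus_mask=None) -> "GLMatrix":
        """Return a new GLMatrix restricted to the masked rows/columns."""
        imask = np.arange(self.n_individuals) if individual_mask is None else np.asarray(individual_mask)
        lmask = np.arange(self.n_loci) if locus_mask is None else np.asarray(locus_mask)
        if imask.dtype == bool:
            imask = np.flatnonzero(imask)
        if lmask.dtype == bool:
            lmask = np.flatnonzero(lmask)
        return GLMatrix(
            individuals=self.individuals[imask],
            loci=self.loci.iloc[lmask].reset_index(drop=True),
            gl=self.gl[np.ix_(imask, lmask)],
            depth=None if self.depth is None else self.depth[np.ix_(imask, lmask)],
        )

    def select_individuals(self, ids) -> "GLMatrix":
        return self.subset(individual_mask=self.indices_of(ids))

    # -- long-format frame dialect ----------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per individual x locus."""
        n, l = self.gl.shape[:2]
        ind = np.repeat(self.individuals, l)
        frame = pd.DataFrame(
            {
                "individual": ind,
                "locus_id": np.tile(self.locus_ids, n),
                "contig": np.tile(self.contigs, n),
                "L0": self.gl[:, :, 0].ravel(),
                "L1": self.gl[:, :, 1].ravel(),
                "L2": self.gl[:, :, 2].ravel(),
            }
        )
        if self.depth is not None:
            frame["depth"] = self.depth.ravel()
        return frame

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "GLMatrix":
        individuals = frame["individual"].drop_duplicates().to_numpy()
        loci = frame.loc[
            ~frame["locus_id"].duplicated(), ["locus_id", "contig"]
        ].reset_index(drop=True)
        n, l = len(individuals), len(loci)
        gl = np.empty((n, l, 3))
        for g in range(3):
            gl[:, :, g] = frame[f"L{g}"].to_numpy().reshape(n, l)
        depth = None
        if "depth" in frame.columns:
            depth = frame["depth"].to_numpy().reshape(n, l)
        return cls(individuals=individuals, loci=loci, gl=gl, depth=depth)


@dataclass
class FilterReport:
    """Bookkeeping for a filtering step: counts in, removed per rule, out."""

    axis: str  # "individuals" or "loci"
    n_input: int
    removed: dict[str, int] = field(default_factory=dict)
    n_output: int = 0

    def __post_init__(self) -> None:
        if self.n_input - sum(self.removed.values()) != self.n_output:
            raise ValueError(
                f"FilterReport does not reconcile: {self.n_input} - "
                f"{sum(self.removed.values())} != {self.n_output}"
            )

    def to_frame(self) -> pd.DataFrame:
        rows = [{"axis": self.axis, "rule": "input", "count": self.n_input}]
        rows += [
            {"axis": self.axis, "rule": f"removed:{name}", "count": n}
            for name, n in self.removed.items()
        ]
        rows.append({"axis": self.axis, "rule": "output", "count": self.n_output})
        return pd.DataFrame(rows)

    def __str__(self) -> str:
        parts = [f"{self.axis}: {self.n_input} in"]
        parts += [f"-{n} ({name})" for name, n in self.removed.items()]
        parts.append(f"{self.n_output} out")
        return " ".join(parts)
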