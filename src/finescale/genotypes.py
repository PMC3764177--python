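"""Data model and I/O for georeferenced multilocus codominant genotypes.

The universal input of the package is a set of diploid individuals with
Cartesian coordinates (metres, arbitrary local frame), a plot label, and an
ordered pair of allele codes per locus.  Allele codes are opaque positive
integers; 0 marks a missing gene copy and a genotype is either fully typed
(both copies positive) or fully missing (both 0), matching the conventions
of SPAGeDi and GenAlEx input files.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


class GenotypeError(ValueError):
    """Raised for malformed or inconsistent genotype data."""


@dataclass
class GeoGenotypes:
    """Georeferenced diploid multilocus genotypes.

    Parameters
    ----------
    ids : sequence of str
        Unique individual identifiers.
    plot : sequence of str
        Plot label per individual.
    x, y : array-like of float
        Coordinates in metres in a shared local Cartesian frame.
    geno : int array, shape (n, L, 2)
        Allele codes; positive integers, 0 = missing.  At every locus the
        two copies are either both 0 or both positive.
    locus_names : sequence of str
        Labels for the L loci.
    """

    ids: list[str]
    plot: np.ndarray
    x: np.ndarray
    y: np.ndarray
    geno: np.ndarray
    locus_names: list[str]

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        self.plot = np.asarray(self.plot, dtype=object)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.geno = np.asarray(self.geno, dtype=np.int64)
        self.locus_names = [str(s) for s in self.locus_names]
        n = len(self.ids)
        if len(set(self.ids)) != n:
            seen: set[str] = set()
            for i in self.ids:
                if i in seen:
                    raise GenotypeError(f"duplicate individual id {i!r}")
                seen.add(i)
        if self.geno.ndim != 3 or self.geno.shape[2] != 2:
            raise GenotypeError("geno must have shape (n, L, 2)")
        if self.geno.shape[0] != n or len(self.plot) != n or len(self.x) != n or len(self.y) != n:
            raise GenotypeError("inconsistent numbers of individuals across fields")
        if self.geno.shape[1] != len(self.locus_names):
            raise GenotypeError("locus_names length does not match geno")
        if self.n_loci < 1:
            raise GenotypeError("need at least one locus")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise GenotypeError("coordinates must be finite")
        if (self.geno < 0).any():
            raise GenotypeError("allele codes must be non-negative")
        half = (self.geno == 0).sum(axis=2) == 1
        if half.any():
            i, l = np.argwhere(half)[0]
            raise GenotypeError(
                f"half-missing genotype for individual {self.ids[i]!r} at locus "
                f"{self.locus_names[l]!r}: alleles must be both 0 or both positive"
            )

    # -- basic accessors -------------------------------------------------

    @property
    def n_ind(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return self.geno.shape[1]

    @property
    def missing(self) -> np.ndarray:
        """Boolean (n, L): genotype missing at a locus."""
        return self.geno[:, :, 0] == 0

    def coords(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def subset(self, index: Sequence[int] | np.ndarray) -> "GeoGenotypes":
        """Return a new dataset restricted to the given individual indices."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        index = index.astype(np.intp, copy=False)
        return GeoGenotypes(
            ids=[self.ids[i] for i in index],
            plot=self.plot[index],
            x=self.x[index],
            y=self.y[index],
            geno=self.geno[index],
            locus_names=list(self.locus_names),
        )

    def plots(self) -> list[str]:
        """Distinct plot labels in order of first appearance."""
        out: list[str] = []
        for p in self.plot:
            if p not in out:
                out.append(p)
        return out


@dataclass
class AlleleFrequencies:
    """Per-locus relative allele frequencies over non-missing gene copies.

    ``freqs[l]`` maps allele code -> relative frequency at locus l;
    ``n_copies[l]`` is the number of gene copies counted;
    ``n_typed[l]`` the number of fully typed individuals.  Loci with zero
    typed copies are listed in ``empty_loci`` (frequencies left empty).
    """

    locus_names: list[str]
    freqs: list[dict[int, float]]
    n_copies: np.ndarray
    n_typed: np.ndarray
    empty_loci: list[str] = field(default_factory=list)

    @property
    def n_loci(self) -> int:
        return len(self.locus_names)

    def alleles(self, locus: int) -> np.ndarray:
        return np.array(sorted(self.freqs[locus]), dtype=np.int64)


def allele_frequencies(g: GeoGenotypes, subset: Sequence[int] | None = None) -> AlleleFrequencies:
    """Observed allele frequencies, optionally over a subset of individuals.

    Loci where every individual of the subset is missing are flagged in
    ``empty_loci`` rather than dropped.
    """
    if subset is None:
        sub = g
    else:
        subset = np.asarray(subset)
        if subset.size == 0:
            raise GenotypeError("subset must be non-empty")
        sub = g.subset(subset)
    freqs: list[dict[int, float]] = []
    n_copies = np.zeros(g.n_loci, dtype=np.int64)
    n_typed = np.zeros(g.n_loci, dtype=np.int64)
    empty: list[str] = []
    for l in range(g.n_loci):
        copies = sub.geno[:, l, :].ravel()
        copies = copies[copies > 0]
        n_copies[l] = copies.size
        n_typed[l] = copies.size // 2
        if copies.size == 0:
            empty.append(g.locus_names[l])
            freqs.append({})
            continue
        vals, counts = np.unique(copies, return_counts=True)
        freqs.append({int(a): c / copies.size for a, c in zip(vals, counts)})
    return AlleleFrequencies(list(g.locus_names), freqs, n_copies, n_typed, empty)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _loci_from_columns(cols: Sequence[str]) -> list[str]:
    allele_cols = [c for c in cols if c not in ("id", "plot", "x", "y")]
    if len(allele_cols) % 2 != 0:
        raise GenotypeError(
            f"odd number of allele columns ({len(allele_cols)}): "
            "each locus needs '<locus>_1' and '<locus>_2'"
        )
    loci = []
    for i in range(0, len(allele_cols), 2):
        c1, c2 = allele_cols[i], allele_cols[i + 1]
        if not (c1.endswith("_1") and c2.endswith("_2") and c1[:-2] == c2[:-2]):
            raise GenotypeError(f"allele columns {c1!r}, {c2!r} are not a '<locus>_1/_2' pair")
        loci.append(c1[:-2])
    return loci


def read_genotypes(path, dialect: str = "plain-csv") -> GeoGenotypes:
    """Read a genotype table.

    ``plain-csv`` expects columns ``id, plot, x, y`` followed by two columns
    per locus named ``<locus>_1`` and ``<locus>_2``.  ``genalex-like``
    accepts the same body preceded by two GenAlEx-style preamble rows
    (counts and title), which are skipped.  Missing alleles may be coded as
    0, empty, or ``NA`` and are normalized to 0.
    """
    if dialect not in ("plain-csv", "genalex-like"):
        raise ValueError(f"unknown dialect {dialect!r}")
    skip = 2 if dialect == "genalex-like" else 0
    try:
        df = pd.read_csv(path, skiprows=skip, dtype=str, keep_default_na=False)
    except pd.errors.ParserError as e:
        raise GenotypeError(f"malformed genotype file {path}: {e}") from None
    for col in ("id", "plot", "x", "y"):
        if col not in df.columns:
            raise GenotypeError(f"missing required column {col!r} in {path}")
    loci = _loci_from_columns(df.columns)
    try:
        x = df["x"].astype(float).to_numpy()
        y = df["y"].astype(float).to_numpy()
    except ValueError as e:
        bad = None
        for i, (vx, vy) in enumerate(zip(df["x"], df["y"])):
            try:
                float(vx), float(vy)
            except ValueError:
                bad = i + 2 + skip  # 1-based line, after header
                break
        raise GenotypeError(f"unparseable coordinate at line {bad} of {path}: {e}") from None
    n = len(df)
    geno = np.zeros((n, len(loci), 2), dtype=np.int64)
    for l, locus in enumerate(loci):
        for k in (0, 1):
            col = f"{locus}_{k + 1}"
            raw = df[col].str.strip().replace({"": "0", "NA": "0", "na": "0", "-": "0"})
            try:
                geno[:, l, k] = raw.astype(int)
            except ValueError:
                bad_rows = [i + 2 + skip for i, v in enumerate(raw) if not v.lstrip("-").isdigit()]
                raise GenotypeError(
                    f"malformed allele value in column {col!r} at line {bad_rows[0]} of {path}"
                ) from None
    # a single missing copy silently masks the whole locus genotype
    half = (geno == 0).any(axis=2)
    geno[half] = 0
    return GeoGenotypes(
        ids=list(df["id"]), plot=df["plot"].to_numpy(dtype=object),
        x=x, y=y, geno=geno, locus_names=loci,
    )


def write_genotypes(g: GeoGenotypes, path) -> None:
    """Write the plain-csv dialect read back by :func:`read_genotypes`."""
    data = {"id": g.ids, "plot": g.plot, "x": g.x, "y": g.y}
    for l, locus in enumerate(g.locus_names):
        data[f"{locus}_1"] = g.geno[:, l, 0]
        data[f"{locus}_2"] = g.geno[:, l, 1]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.6f")


def write_spagedi(g: GeoGenotypes, path, digits: int = 3) -> None:
    """Export to the SPAGeDi text format.

    Header line: ``n_ind n_cat n_coord n_loci digits ploidy``; the category
    column carries the plot label; each genotype field concatenates the two
    zero-padded allele codes of a locus.  The file is terminated by ``END``.
    """
    if g.n_ind == 0:
        raise GenotypeError("cannot export an empty dataset")
    if (g.geno >= 10 ** digits).any():
        bad = int(g.geno.max())
        raise GenotypeError(f"allele code {bad} does not fit in {digits} digits")
    buf = io.StringIO()
    buf.write(f"{g.n_ind}\t{len(g.plots())}\t2\t{g.n_loci}\t{digits}\t2\n")
    buf.write("0\n")  # no distance intervals declared
    buf.write("Ind\tCat\tX\tY\t" + "\t".join(g.locus_names) + "\n")
    for i in range(g.n_ind):
        fields = [g.ids[i], str(g.plot[i]), f"{g.x[i]:.6f}", f"{g.y[i]:.6f}"]
        for l in range(g.n_loci):
            a, b = g.geno[i, l]
            fields.append(f"{a:0{digits}d}{b:0{digits}d}")
        buf.write("\t".join(fields) + "\n")
    buf.write("END\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")
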