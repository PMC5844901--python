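"""Readers and writers for the external representations used by the pipeline.

Genotype tables are tab-separated text with one row per individual::

    sample  sex     population      DXS8378 DXS10135 ...
    M001    M       Mongolian       10      21       ...
    F001    F       Mongolian       10/11   19/21    ...

Females carry two alleles separated by ``/``, males one; ``.`` marks a
missing genotype.  Allele labels follow STR nomenclature: an integer repeat
count with an optional microvariant suffix (``24.1`` = 24 repeats plus one
base).

Also provided: labelled distance matrices (PHYLIP square or CSV), Newick
trees and an allele-frequency CSV.
"""

from __future__ import annotations

import csv
import io
import logging
import math
import re
from dataclasses import dataclass, field
from functools import total_ordering
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np

logger = logging.getLogger(__name__)

MISSING = "."
ALLELE_SEP = "/"

#: Columns ignored on read (genotyped by the kit but never analysed).
IGNORED_COLUMNS = frozenset({"amelogenin", "amel"})

_ALLELE_RE = re.compile(r"^(\d+)(?:\.(\d+))?$")


class FormatError(ValueError):
    """Malformed external data; carries row/column coordinates when known."""

    def __init__(self, message: str, row: int | None = None, column: str | None = None):
        loc = ""
        if row is not None:
            loc += f" [row {row}]"
        if column is not None:
            loc += f" [column {column}]"
        super().__init__(message + loc)
        self.row = row
        self.column = column


@total_ordering
@dataclass(frozen=True)
class AlleleLabel:
    """An STR allele designation such as ``21`` or ``24.1``.

    Ordering is by numeric key (repeat count, then microvariant part), which
    is total, and ``str()`` round-trips the original text.
    """

    repeat: int
    variant: int = 0

    @classmethod
    def parse(cls, text: str) -> "AlleleLabel":
        m = _ALLELE_RE.match(text.strip())
        if not m:
            raise FormatError(f"invalid allele label {text!r}")
        return cls(int(m.group(1)), int(m.group(2)) if m.group(2) else 0)

    @property
    def key(self) -> tuple[int, int]:
        return (self.repeat, self.variant)

    def __str__(self) -> str:
        return f"{self.repeat}.{self.variant}" if self.variant else str(self.repeat)

    def __lt__(self, other: "AlleleLabel") -> bool:
        return self.key < other.key


Genotype = tuple[AlleleLabel, ...]  # length 1 (male) or 2 (female); None if missing


@dataclass
class Individual:
    sample_id: str
    sex: str  # 'M' or 'F'
    population: str
    genotypes: dict[str, Genotype | None]

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise FormatError(f"unknown sex code {self.sex!r} for sample {self.sample_id!r}")
        expected = 1 if self.sex == "M" else 2
        for locus, g in self.genotypes.items():
            if g is not None and len(g) != expected:
                raise FormatError(
                    f"sample {self.sample_id!r} ({self.sex}) has {len(g)} allele(s) at "
                    f"{locus}, expected {expected}",
                    column=locus,
                )


@dataclass
class GenotypeTable:
    """Individuals x loci with sex and population labels.

    Males are hemizygous (one allele per locus), females diploid (an
    unordered pair).  Sample ids are unique; every genotype's locus appears
    in ``loci``.
    """

    loci: list[str]
    individuals: list[Individual] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        locus_set = set(self.loci)
        for ind in self.individuals:
            if ind.sample_id in seen:
                raise FormatError(f"duplicate sample id {ind.sample_id!r}")
            seen.add(ind.sample_id)
            extra = set(ind.genotypes) - locus_set
            if extra:
                raise FormatError(
                    f"sample {ind.sample_id!r} has genotypes at undeclared loci {sorted(extra)}"
                )

    def __len__(self) -> int:
        return len(self.individuals)

    @property
    def populations(self) -> list[str]:
        out: list[str] = []
        for ind in self.individuals:
            if ind.population not in out:
                out.append(ind.population)
        return out

    def subset(self, *, sex: str | None = None, population: str | None = None) -> "GenotypeTable":
        rows = [
            ind
            for ind in self.individuals
            if (sex is None or ind.sex == sex)
            and (population is None or ind.population == population)
        ]
        return GenotypeTable(list(self.loci), rows)

    def males(self) -> "GenotypeTable":
        return self.subset(sex="M")

    def females(self) -> "GenotypeTable":
        return self.subset(sex="F")


@dataclass(frozen=True)
class LinkageGroupDef:
    """A named triple of physically clustered loci analysed as one haplotype."""

    name: str
    loci: tuple[str, str, str]

    def __post_init__(self) -> None:
        if len(set(self.loci)) != len(self.loci):
            raise ValueError(f"linkage group {self.name}: loci must be distinct")


#: The four Argus X-12 linkage groups in physical order along the chromosome.
DEFAULT_LINKAGE_GROUPS: tuple[LinkageGroupDef, ...] = (
    LinkageGroupDef("LG1", ("DXS8378", "DXS10135", "DXS10148")),
    LinkageGroupDef("LG2", ("DXS7132", "DXS10074", "DXS10079")),
    LinkageGroupDef("LG3", ("DXS10101", "DXS10103", "HPRTB")),
    LinkageGroupDef("LG4", ("DXS7423", "DXS10134", "DXS10146")),
)

ARGUS_X12_LOCI: tuple[str, ...] = tuple(l for lg in DEFAULT_LINKAGE_GROUPS for l in lg.loci)


# ---------------------------------------------------------------------------
# genotype tables
# ---------------------------------------------------------------------------

def _as_text_stream(source: str | Path | TextIO) -> TextIO:
    if isinstance(source, (str, Path)):
        return open(source, "r", encoding="utf-8", newline="")
    return source


def read_genotype_table(source: str | Path | TextIO, delimiter: str = "\t") -> GenotypeTable:
    """Parse a genotype table; malformed cells raise :class:`FormatError`
    carrying row and column coordinates.  Missing cells (``.``) are kept as
    missing, never dropped."""
    stream = _as_text_stream(source)
    reader = csv.reader(stream, delimiter=delimiter)
    try:
        header = next(reader)
    except StopIteration:
        raise FormatError("empty genotype file") from None
    header = [h.strip() for h in header]
    if len(header) < 3 or [h.lower() for h in header[:3]] != ["sample", "sex", "population"]:
        raise FormatError("header must start with: sample, sex, population")
    loci: list[str] = []
    keep: list[int] = []
    for idx, name in enumerate(header[3:], start=3):
        if name.lower() in IGNORED_COLUMNS:
            logger.warning("ignoring non-STR column %r", name)
            continue
        loci.append(name)
        keep.append(idx)

    individuals: list[Individual] = []
    for rownum, row in enumerate(reader, start=2):
        if not row or all(not c.strip() for c in row):
            continue
        if len(row) != len(header):
            raise FormatError(
                f"expected {len(header)} fields, found {len(row)}", row=rownum
            )
        sample_id, sex, pop = (row[0].strip(), row[1].strip(), row[2].strip())
        genotypes: dict[str, Genotype | None] = {}
        for locus, idx in zip(loci, keep):
            cell = row[idx].strip()
            if cell == MISSING or cell == "":
                genotypes[locus] = None
                continue
            parts = cell.split(ALLELE_SEP)
            try:
                alleles = tuple(AlleleLabel.parse(p) for p in parts)
            except FormatError as exc:
                raise FormatError(str(exc), row=rownum, column=locus) from None
            if sex == "M" and len(alleles) != 1:
                raise FormatError(
                    f"male sample {sample_id!r} has {len(alleles)} alleles",
                    row=rownum, column=locus,
                )
            if sex == "F" and len(alleles) != 2:
                raise FormatError(
                    f"female sample {sample_id!r} has {len(alleles)} allele(s)",
                    row=rownum, column=locus,
                )
            genotypes[locus] = alleles
        try:
            individuals.append(Individual(sample_id, sex, pop, genotypes))
        except FormatError as exc:
            raise FormatError(str(exc), row=rownum) from None
    table = GenotypeTable(loci, individuals)
    if isinstance(source, (str, Path)):
        stream.close()
    return table


def format_genotype(g: Genotype | None) -> str:
    if g is None:
        return MISSING
    return ALLELE_SEP.join(str(a) for a in sorted(g))


def write_genotype_table(table: GenotypeTable, dest: str | Path | TextIO | None = None,
                         delimiter: str = "\t") -> str:
    """Serialize canonically: female pairs smaller allele first, ``.`` for
    missing.  Returns the text (and writes it to *dest* if given)."""
    buf = io.StringIO()
    buf.write(delimiter.join(["sample", "sex", "population", *table.loci]) + "\n")
    for ind in table.individuals:
        cells = [ind.sample_id, ind.sex, ind.population]
        for locus in table.loci:
            cells.append(format_genotype(ind.genotypes.get(locus)))
        buf.write(delimiter.join(cells) + "\n")
    text = buf.getvalue()
    if dest is not None:
        if isinstance(dest, (str, Path)):
            Path(dest).write_text(text, encoding="utf-8")
        else:
            dest.write(text)
    return text


# ---------------------------------------------------------------------------
# allele-frequency CSV
# ---------------------------------------------------------------------------

def write_frequency_csv(entries: Iterable[tuple[str, str, AlleleLabel, int, float]],
                        dest: str | Path | TextIO | None = None,
                        precision: int = 4) -> str:
    """Rows of (locus, population, allele, count, frequency)."""
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(["locus", "population", "allele", "count", "frequency"])
    for locus, pop, allele, count, freq in entries:
        w.writerow([locus, pop, str(allele), count, f"{freq:.{precision}f}"])
    text = buf.getvalue()
    if dest is not None:
        if isinstance(dest, (str, Path)):
            Path(dest).write_text(text, encoding="utf-8")
        else:
            dest.write(text)
    return text


def read_frequency_csv(source: str | Path | TextIO) -> list[tuple[str, str, AlleleLabel, int, float]]:
    stream = _as_text_stream(source)
    reader = csv.reader(stream)
    header = next(reader)
    if [h.strip().lower() for h in header] != ["locus", "population", "allele", "count", "frequency"]:
        raise FormatError("unexpected frequency CSV header")
    out = []
    for rownum, row in enumerate(reader, start=2):
        if not row:
            continue
        try:
            out.append((row[0], row[1], AlleleLabel.parse(row[2]), int(row[3]), float(row[4])))
        except (ValueError, FormatError) as exc:
            raise FormatError(f"bad frequency row: {exc}", row=rownum) from None
    if isinstance(source, (str, Path)):
        stream.close()
    return out


# ---------------------------------------------------------------------------
# distance matrices
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Symmetric labelled distance matrix with a zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        if np.isnan(self.values).any():
            raise FormatError("distance matrix contains NaN")
        if np.abs(self.values - self.values.T).max(initial=0.0) > 1e-8:
            raise FormatError("distance matrix asymmetry exceeds 1e-8")
        # canonicalize: exact symmetry, exact zero diagonal
        self.values = (self.values + self.values.T) / 2.0
        np.fill_diagonal(self.values, 0.0)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    @property
    def n(self) -> int:
        return len(self.labels)


def read_distance_matrix(source: str | Path | TextIO) -> DistanceMatrix:
    """Read a PHYLIP square matrix or a labelled CSV (sniffed from line 1)."""
    stream = _as_text_stream(source)
    text = stream.read()
    if isinstance(source, (str, Path)):
        stream.close()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise FormatError("empty distance matrix")
    first = lines[0].split()
    if len(first) == 1 and first[0].isdigit():  # PHYLIP square
        n = int(first[0])
        labels, rows = [], []
        if len(lines) - 1 != n:
            raise FormatError(f"PHYLIP matrix declares {n} rows, found {len(lines) - 1}")
        for ln in lines[1:]:
            parts = ln.split()
            if len(parts) != n + 1:
                raise FormatError(f"non-square PHYLIP row: {ln!r}")
            labels.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
        return DistanceMatrix(labels, np.array(rows))
    # labelled CSV: header = ,L1,L2,... then one row per label
    reader = csv.reader(io.StringIO(text))
    header = next(reader)
    labels = [h.strip() for h in header[1:]]
    rows = []
    for row in reader:
        if not row:
            continue
        if len(row) != len(labels) + 1:
            raise FormatError(f"non-square CSV row: {row!r}")
        rows.append([float(x) for x in row[1:]])
    if len(rows) != len(labels):
        raise FormatError("CSV distance matrix is not square")
    return DistanceMatrix(labels, np.array(rows))


def write_distance_matrix(m: DistanceMatrix, dest: str | Path | TextIO | None = None,
                          dialect: str = "phylip", precision: int = 8) -> str:
    if dialect == "phylip":
        lines = [str(m.n)]
        width = max(len(l) for l in m.labels) + 2
        for label, row in zip(m.labels, m.values):
            lines.append(label.ljust(width) + " ".join(f"{x:.{precision}f}" for x in row))
        text = "\n".join(lines) + "\n"
    elif dialect == "csv":
        buf = io.StringIO()
        w = csv.writer(buf, lineterminator="\n")
        w.writerow([""] + m.labels)
        for label, row in zip(m.labels, m.values):
            w.writerow([label] + [f"{x:.{precision}f}" for x in row])
        text = buf.getvalue()
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if dest is not None:
        if isinstance(dest, (str, Path)):
            Path(dest).write_text(text, encoding="utf-8")
        else:
            dest.write(text)
    return text


# ---------------------------------------------------------------------------
# trees and Newick
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    """Node of a rooted tree; ``length`` is the branch to the parent
    (None at the root)."""

    name: str | None = None
    length: float | None = None
    children: list["TreeNode"] = field(default_factory=list)
    height: float = 0.0  # distance to the leaves for ultrametric trees

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf():
            return [self]
        return [leaf for child in self.children for leaf in child.leaves()]

    def edges(self) -> list[tuple["TreeNode", "TreeNode"]]:
        out = []
        for child in self.children:
            out.append((self, child))
            out.extend(child.edges())
        return out


Tree = TreeNode  # the root node stands for the whole tree


def write_newick(tree: TreeNode, precision: int = 6) -> str:
    """Serialize to Newick; every leaf must be named and every non-root edge
    must carry a branch length."""

    def fmt(node: TreeNode, is_root: bool) -> str:
        if node.is_leaf():
            if not node.name:
                raise FormatError("unnamed leaf cannot be serialized")
            base = node.name
        else:
            base = "(" + ",".join(fmt(c, False) for c in node.children) + ")"
            if node.name:
                base += node.name
        if not is_root:
            if node.length is None:
                raise FormatError("missing branch length on a non-root edge")
            base += f":{_trim(node.length, precision)}"
        return base

    return fmt(tree, True) + ";"


def _trim(x: float, precision: int) -> str:
    s = f"{x:.{precision}f}"
    s = s.rstrip("0").rstrip(".")
    return s if s else "0"


def read_newick(text: str | TextIO) -> TreeNode:
    """Parse Newick via scikit-bio and convert to :class:`TreeNode`."""
    from skbio import TreeNode as SkbioNode  # deferred: heavy import

    if not isinstance(text, str):
        text = text.read()
    sk = SkbioNode.read(io.StringIO(text), format="newick")

    def convert(node) -> TreeNode:
        out = TreeNode(name=node.name,
                       length=float(node.length) if node.length is not None else None)
        out.children = [convert(c) for c in node.children]
        return out

    root = convert(sk)
    # heights from branch lengths (max leaf depth below each node)
    def set_heights(node: TreeNode) -> float:
        if node.is_leaf():
            node.height = 0.0
        else:
            node.height = max((c.height + (c.length or 0.0)) for c in map_set(node))
        return node.height

    def map_set(node):
        for c in node.children:
            set_heights(c)
            yield c

    set_heights(root)
    return root
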