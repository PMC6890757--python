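"""Readers, writers and domain containers for annotation, scaffold, tree and
count-matrix inputs.

Coordinate contract
-------------------
All in-memory intervals are 0-based, half-open ``[start, end)`` so that
``length == end - start`` with no off-by-one ambiguity. On disk, GFF3 is
1-based inclusive and BED is 0-based half-open; the readers and writers
convert at the boundary (``gff_start = bed_start + 1``, ``gff_end = bed_end``).

Strand is parsed where present but carried as metadata only: none of the
downstream statistics are strand-aware.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO

__all__ = [
    "TERecord",
    "GeneRecord",
    "ScaffoldTable",
    "SupportTree",
    "SuperfamilyCountMatrix",
    "AnnotationParseError",
    "read_te_annotations",
    "write_te_annotations",
    "read_gene_annotations",
    "read_scaffolds",
    "read_support_tree",
    "parse_support_tree",
    "read_count_matrix",
]


class AnnotationParseError(ValueError):
    """A record-level input error, carrying the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


@dataclass(frozen=True)
class TERecord:
    """One clade-labeled transposable-element interval on a scaffold."""

    scaffold_id: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    clade: str
    family: str = ""
    source_id: str = ""
    strand: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.scaffold_id}"
            )
        if not self.clade:
            raise ValueError("clade label must be nonempty")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneRecord:
    """A predicted gene interval, flagged as TE-coding or not."""

    scaffold_id: str
    start: int
    end: int
    gene_id: str
    is_te: bool = False
    product_label: str = ""
    strand: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) for gene {self.gene_id}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


class ScaffoldTable:
    """Scaffold lengths, optionally backed by sequences (FASTA mode)."""

    def __init__(
        self,
        lengths: Mapping[str, int],
        sequences: Mapping[str, str] | None = None,
    ):
        if not lengths:
            raise ValueError("scaffold table is empty")
        for sid, length in lengths.items():
            if length <= 0:
                raise ValueError(f"scaffold {sid} has non-positive length {length}")
        self._lengths: dict[str, int] = dict(lengths)
        self._sequences = dict(sequences) if sequences is not None else None
        if self._sequences is not None:
            for sid, seq in self._sequences.items():
                if len(seq) != self._lengths.get(sid):
                    raise ValueError(f"sequence/length mismatch for scaffold {sid}")

    @property
    def lengths(self) -> Mapping[str, int]:
        return dict(self._lengths)

    @property
    def total_length(self) -> int:
        return sum(self._lengths.values())

    @property
    def has_sequences(self) -> bool:
        return self._sequences is not None

    def __contains__(self, scaffold_id: str) -> bool:
        return scaffold_id in self._lengths

    def __len__(self) -> int:
        return len(self._lengths)

    def __iter__(self) -> Iterator[str]:
        return iter(self._lengths)

    def length_of(self, scaffold_id: str) -> int:
        return self._lengths[scaffold_id]

    def sequence(self, scaffold_id: str) -> str:
        if self._sequences is None:
            raise ValueError("scaffold table was built from lengths only (no sequences)")
        return self._sequences[scaffold_id]

    def validate_records(self, records: Iterable[TERecord | GeneRecord]) -> None:
        """Check every record lies on a known scaffold within its length."""
        for rec in records:
            if rec.scaffold_id not in self._lengths:
                raise ValueError(f"record on unknown scaffold {rec.scaffold_id}")
            if rec.end > self._lengths[rec.scaffold_id]:
                raise ValueError(
                    f"record [{rec.start}, {rec.end}) exceeds scaffold "
                    f"{rec.scaffold_id} length {self._lengths[rec.scaffold_id]}"
                )


class SupportTree:
    """A rooted tree whose internal nodes carry support values in [0, 1].

    Supports are stored on each dendropy node as ``node.support`` (``None``
    when the input had no label). Files on a 0-100 bootstrap scale are
    normalized on a whole-file basis: any value > 1 anywhere means the whole
    file is percent-scaled and every support is divided by 100. Mixed scales
    within one file are a data error by that rule and surface as an
    out-of-range support.
    """

    def __init__(self, tree: dendropy.Tree):
        tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(tips) < 2:
            raise ValueError("tree must have at least 2 tips")
        if len(set(tips)) != len(tips):
            dupes = sorted({t for t in tips if tips.count(t) > 1})
            raise ValueError(f"duplicate tip labels: {dupes}")
        for node in tree.preorder_node_iter():
            if not hasattr(node, "support"):
                node.support = None
        self.tree = tree

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def internal_supports(self) -> list[float | None]:
        """Supports of internal non-root nodes, in preorder."""
        root = self.tree.seed_node
        return [
            node.support
            for node in self.tree.preorder_node_iter()
            if not node.is_leaf() and node is not root
        ]

    def as_newick(self) -> str:
        """Serialize with supports written back as internal-node labels."""
        for node in self.tree.preorder_node_iter():
            if not node.is_leaf():
                node.label = (
                    None if node.support is None else format(node.support, "g")
                )
        return self.tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        ).strip()

    def clone(self) -> "SupportTree":
        return parse_support_tree(self.as_newick())


class SuperfamilyCountMatrix:
    """Integer gene counts, superfamilies (rows) x genera (columns)."""

    def __init__(
        self,
        counts: pd.DataFrame,
        names: Mapping[str, str] | None = None,
    ):
        if counts.shape[1] < 2:
            raise ValueError(
                "count matrix needs >= 2 genera (the score mean is over genera)"
            )
        if (counts.values < 0).any():
            raise ValueError("count matrix contains negative cells")
        self.counts = counts.astype(int)
        self.names = dict(names) if names is not None else {}

    @property
    def superfamilies(self) -> list[str]:
        return list(self.counts.index)

    @property
    def genera(self) -> list[str]:
        return list(self.counts.columns)

    def row(self, superfamily: str) -> dict[str, int]:
        return self.counts.loc[superfamily].to_dict()

    def name_of(self, superfamily: str) -> str:
        return self.names.get(superfamily, "")


# ---------------------------------------------------------------------------
# annotation I/O


def _parse_gff3_attributes(column9: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for token in column9.strip().split(";"):
        token = token.strip()
        if not token:
            continue
        if "=" not in token:
            continue
        key, _, value = token.partition("=")
        attrs[key.strip()] = value.strip()
    return attrs


def _parse_bed_name(column4: str) -> dict[str, str]:
    # BED column 4 carries "clade=oryco" or "clade=oryco;family=Ty1/Copia;id=x"
    return _parse_gff3_attributes(column4)


def read_te_annotations(
    path: str | Path,
    format: str = "gff3",
    clade_key: str = "clade",
) -> list[TERecord]:
    """Read clade-labeled TE intervals from GFF3 or BED.

    GFF3 coordinates (1-based inclusive) are converted to the internal
    0-based half-open convention; BED coordinates pass through. The clade is
    taken from the GFF3 column-9 attribute / BED column-4 tag named
    ``clade_key``; a record without it is an error naming the line.
    """
    if format not in ("gff3", "bed"):
        raise ValueError(f"unknown annotation format {format!r}")
    records: list[TERecord] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if format == "gff3":
                if len(fields) < 9:
                    raise AnnotationParseError(
                        f"GFF3 line has {len(fields)} columns, expected 9", lineno
                    )
                scaffold_id = fields[0]
                try:
                    gff_start, gff_end = int(fields[3]), int(fields[4])
                except ValueError:
                    raise AnnotationParseError("non-integer coordinates", lineno)
                start, end = gff_start - 1, gff_end
                strand = fields[6] if fields[6] in ("+", "-") else None
                attrs = _parse_gff3_attributes(fields[8])
            else:
                if len(fields) < 4:
                    raise AnnotationParseError(
                        f"BED line has {len(fields)} columns, expected >= 4", lineno
                    )
                scaffold_id = fields[0]
                try:
                    start, end = int(fields[1]), int(fields[2])
                except ValueError:
                    raise AnnotationParseError("non-integer coordinates", lineno)
                strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else None
                attrs = _parse_bed_name(fields[3])
            if clade_key not in attrs:
                raise AnnotationParseError(
                    f"missing {clade_key!r} attribute", lineno
                )
            if start >= end:
                raise AnnotationParseError(
                    f"start >= end ({start} >= {end})", lineno
                )
            if start < 0:
                raise AnnotationParseError(f"negative start {start}", lineno)
            records.append(
                TERecord(
                    scaffold_id=scaffold_id,
                    start=start,
                    end=end,
                    clade=attrs[clade_key],
                    family=attrs.get("family", ""),
                    source_id=attrs.get("ID", attrs.get("id", "")),
                    strand=strand,
                )
            )
    return records


def write_te_annotations(
    records: Sequence[TERecord],
    path: str | Path,
    format: str = "gff3",
    clade_key: str = "clade",
) -> None:
    """Write TE records; inverse of :func:`read_te_annotations` per format."""
    if format not in ("gff3", "bed"):
        raise ValueError(f"unknown annotation format {format!r}")
    with open(path, "w") as handle:
        if format == "gff3":
            handle.write("##gff-version 3\n")
            for rec in records:
                attrs = [f"{clade_key}={rec.clade}"]
                if rec.family:
                    attrs.append(f"family={rec.family}")
                if rec.source_id:
                    attrs.append(f"ID={rec.source_id}")
                handle.write(
                    "\t".join(
                        [
                            rec.scaffold_id,
                            "cladescape",
                            "transposable_element",
                            str(rec.start + 1),
                            str(rec.end),
                            ".",
                            rec.strand or ".",
                            ".",
                            ";".join(attrs),
                        ]
                    )
                    + "\n"
                )
        else:
            for rec in records:
                name = [f"{clade_key}={rec.clade}"]
                if rec.family:
                    name.append(f"family={rec.family}")
                if rec.source_id:
                    name.append(f"id={rec.source_id}")
                fields = [
                    rec.scaffold_id,
                    str(rec.start),
                    str(rec.end),
                    ";".join(name),
                ]
                if rec.strand:
                    fields += ["0", rec.strand]
                handle.write("\t".join(fields) + "\n")


def read_gene_annotations(
    path: str | Path,
    te_key: str = "is_te",
    product_key: str = "product",
) -> list[GeneRecord]:
    """Read predicted genes from GFF3 with a TE/non-TE flag attribute."""
    records: list[GeneRecord] = []
    seen_ids: set[str] = set()
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise AnnotationParseError(
                    f"GFF3 line has {len(fields)} columns, expected 9", lineno
                )
            try:
                start, end = int(fields[3]) - 1, int(fields[4])
            except ValueError:
                raise AnnotationParseError("non-integer coordinates", lineno)
            if start >= end or start < 0:
                raise AnnotationParseError(f"bad interval [{start}, {end})", lineno)
            attrs = _parse_gff3_attributes(fields[8])
            gene_id = attrs.get("ID", "")
            if not gene_id:
                raise AnnotationParseError("gene record lacks ID attribute", lineno)
            if gene_id in seen_ids:
                raise AnnotationParseError(f"duplicate gene ID {gene_id!r}", lineno)
            seen_ids.add(gene_id)
            records.append(
                GeneRecord(
                    scaffold_id=fields[0],
                    start=start,
                    end=end,
                    gene_id=gene_id,
                    is_te=attrs.get(te_key, "false").lower() in ("1", "true", "yes"),
                    product_label=attrs.get(product_key, ""),
                    strand=fields[6] if fields[6] in ("+", "-") else None,
                )
            )
    return records


# ---------------------------------------------------------------------------
# scaffolds


def read_scaffolds(path: str | Path, mode: str = "fasta") -> ScaffoldTable:
    """Build a :class:`ScaffoldTable` from FASTA (with sequences) or a
    two-column ``scaffold_id<TAB>length`` TSV (lengths only)."""
    if mode == "fasta":
        lengths: dict[str, int] = {}
        sequences: dict[str, str] = {}
        for record in SeqIO.parse(str(path), "fasta"):
            if record.id in lengths:
                raise ValueError(f"duplicate scaffold id {record.id!r}")
            seq = str(record.seq).upper()
            lengths[record.id] = len(seq)
            sequences[record.id] = seq
        if not lengths:
            raise ValueError(f"no FASTA records in {path}")
        return ScaffoldTable(lengths, sequences)
    if mode == "lengths_tsv":
        lengths = {}
        with open(path) as handle:
            for lineno, line in enumerate(handle, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise AnnotationParseError("expected id<TAB>length", lineno)
                sid = fields[0]
                if sid in lengths:
                    raise AnnotationParseError(f"duplicate scaffold id {sid!r}", lineno)
                try:
                    lengths[sid] = int(fields[1])
                except ValueError:
                    raise AnnotationParseError(f"non-integer length {fields[1]!r}", lineno)
        if not lengths:
            raise ValueError(f"no scaffold lengths in {path}")
        return ScaffoldTable(lengths)
    raise ValueError(f"unknown scaffold mode {mode!r}")


# ---------------------------------------------------------------------------
# trees


def parse_support_tree(newick: str) -> SupportTree:
    """Parse a Newick string whose internal-node labels are support values."""
    try:
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise ValueError(f"could not parse Newick tree: {exc}") from exc

    raw: dict[int, float | None] = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        value: float | None = None
        if node.label is not None and node.label.strip():
            try:
                value = float(node.label)
            except ValueError:
                value = None  # a name, not a support
        raw[id(node)] = value

    values = [v for v in raw.values() if v is not None]
    percent_scaled = any(v > 1 for v in values)
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            node.support = None
            continue
        value = raw[id(node)]
        if value is not None and percent_scaled:
            value = value / 100.0
        if value is not None and not (0.0 <= value <= 1.0):
            raise ValueError(
                f"support {value} out of [0, 1] after normalization "
                "(mixed support scales in one file?)"
            )
        node.support = value
    return SupportTree(tree)


def read_support_tree(path: str | Path) -> SupportTree:
    with open(path) as handle:
        return parse_support_tree(handle.read())


# ---------------------------------------------------------------------------
# count matrices


def read_count_matrix(path: str | Path) -> SuperfamilyCountMatrix:
    """Read a TSV count matrix: header of genus labels, first two columns
    are the superfamily id and name, remaining cells nonnegative integers."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 4:
        raise ValueError(
            "count matrix needs id, name and >= 2 genus columns "
            f"(got {df.shape[1]} columns)"
        )
    id_col, name_col = df.columns[0], df.columns[1]
    genera = list(df.columns[2:])
    counts = pd.DataFrame(index=df[id_col].values, columns=genera, dtype=int)
    for i, row in df.iterrows():
        for genus in genera:
            cell = row[genus]
            try:
                value = int(cell)
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-integer cell {cell!r} at row {row[id_col]!r}, column {genus!r}"
                )
            if value < 0:
                raise ValueError(
                    f"negative cell {value} at row {row[id_col]!r}, column {genus!r}"
                )
            counts.loc[row[id_col], genus] = value
    names = dict(zip(df[id_col].values, df[name_col].values))
    return SuperfamilyCountMatrix(counts, names)
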