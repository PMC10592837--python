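"""AIRR Rearrangement, FASTA and Newick input/output.

AIRR column names follow the AIRR Rearrangement schema verbatim; extra
columns pass through untouched. Sequences are upper-cased on read and any
IUPAC ambiguity code other than N is mapped to N with a warning. Both IMGT
gap characters ``.`` and ``-`` are accepted and treated as non-informative
downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

import dendropy
import pandas as pd

from .tree import GERMLINE_LABEL, Node, PhyloTree

__all__ = [
    "Rearrangement",
    "CellBundle",
    "AirrValidationError",
    "NewickParseError",
    "read_airr",
    "write_airr",
    "group_cells",
    "read_newick",
    "write_newick",
    "write_fasta",
]

REQUIRED_COLUMNS = (
    "sequence_id",
    "locus",
    "v_call",
    "j_call",
    "junction_length",
    "sequence_alignment",
    "germline_alignment",
    "clone_id",
)

VALID_CHARS = set("ACGTN.-")
_IUPAC = set("RYSWKMBDHV")


class AirrValidationError(ValueError):
    pass


class NewickParseError(ValueError):
    pass


@dataclass
class Rearrangement:
    """One chain's annotated, IMGT-gapped sequence record (an AIRR row)."""

    sequence_id: str
    locus: str
    v_call: str
    j_call: str
    junction_length: int
    sequence_alignment: str
    germline_alignment: str
    clone_id: str
    cell_id: Optional[str] = None
    extras: dict = field(default_factory=dict)

    @property
    def is_heavy(self) -> bool:
        return self.locus == "IGH"

    @property
    def v_genes(self) -> tuple[str, ...]:
        return _gene_list(self.v_call)

    @property
    def j_genes(self) -> tuple[str, ...]:
        return _gene_list(self.j_call)

    def validate(self) -> list[str]:
        problems = []
        if self.locus not in ("IGH", "IGK", "IGL"):
            problems.append(f"unknown locus {self.locus!r}")
        if len(self.sequence_alignment) != len(self.germline_alignment):
            problems.append(
                "sequence_alignment and germline_alignment lengths differ "
                f"({len(self.sequence_alignment)} vs {len(self.germline_alignment)})"
            )
        if not self.v_genes:
            problems.append("empty v_call")
        if not self.j_genes:
            problems.append("empty j_call")
        if self.junction_length < 0:
            problems.append("negative junction_length")
        return problems


def _gene_list(call: str) -> tuple[str, ...]:
    """Gene-level names from a comma-separated call, allele suffix stripped."""
    genes = []
    for token in str(call).split(","):
        token = token.strip().split("*")[0]
        if token and token not in genes:
            genes.append(token)
    return tuple(genes)


def _clean_sequence(seq: str, sequence_id: str, column: str) -> str:
    seq = seq.upper()
    bad = set(seq) - VALID_CHARS
    if bad:
        if bad - _IUPAC:
            raise AirrValidationError(
                f"{sequence_id}: invalid characters {sorted(bad - _IUPAC)} in {column}"
            )
        warnings.warn(
            f"{sequence_id}: IUPAC ambiguity codes {sorted(bad)} in {column} mapped to N",
            stacklevel=3,
        )
        seq = "".join("N" if c in _IUPAC else c for c in seq)
    return seq


@dataclass
class CellBundle:
    """One cell: exactly one heavy chain, light-chain candidates (usually <=1).

    ``lights`` may hold several rearrangements when a cell expresses multiple
    or ambiguous light chains; subgroup resolution picks the one consistent
    with the assigned subgroup, after which ``light`` is unambiguous.
    """

    cell_id: str
    heavy: Rearrangement
    lights: tuple[Rearrangement, ...] = ()

    @property
    def light(self) -> Optional[Rearrangement]:
        return self.lights[0] if self.lights else None

    @property
    def has_light(self) -> bool:
        return bool(self.lights)


def read_airr(path, on_invalid: str = "warn") -> list[Rearrangement]:
    """Read an AIRR Rearrangement TSV.

    Rows violating record invariants are dropped with a warning naming the
    row number (``on_invalid="warn"``), or raise (``on_invalid="raise"``).
    A missing required column is always a hard error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise AirrValidationError(f"missing required column(s): {', '.join(missing)}")
    known = set(REQUIRED_COLUMNS) | {"cell_id"}
    records = []
    for row_number, row in enumerate(df.itertuples(index=False), start=2):
        data = dict(zip(df.columns, row))
        try:
            junction_length = int(data["junction_length"] or 0)
        except ValueError:
            junction_length = -1
        rec = Rearrangement(
            sequence_id=data["sequence_id"],
            locus=data["locus"],
            v_call=data["v_call"],
            j_call=data["j_call"],
            junction_length=junction_length,
            sequence_alignment=_clean_sequence(
                data["sequence_alignment"], data["sequence_id"], "sequence_alignment"
            ),
            germline_alignment=_clean_sequence(
                data["germline_alignment"], data["sequence_id"], "germline_alignment"
            ),
            clone_id=data["clone_id"],
            cell_id=data.get("cell_id") or None,
            extras={k: v for k, v in data.items() if k not in known},
        )
        problems = rec.validate()
        if problems:
            message = f"row {row_number} ({rec.sequence_id}): " + "; ".join(problems)
            if on_invalid == "raise":
                raise AirrValidationError(message)
            warnings.warn(message, stacklevel=2)
            continue
        records.append(rec)
    return records


def write_airr(records: Iterable[Rearrangement], path) -> None:
    rows = []
    for rec in records:
        row = {
            "sequence_id": rec.sequence_id,
            "cell_id": rec.cell_id or "",
            "locus": rec.locus,
            "v_call": rec.v_call,
            "j_call": rec.j_call,
            "junction_length": rec.junction_length,
            "sequence_alignment": rec.sequence_alignment,
            "germline_alignment": rec.germline_alignment,
            "clone_id": rec.clone_id,
        }
        row.update(rec.extras)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def group_cells(
    records: list[Rearrangement],
) -> tuple[list[CellBundle], list[Rearrangement]]:
    """Bundle rearrangements by cell.

    Cells with more than one heavy chain are removed entirely; light chains
    with no same-cell heavy chain are rejected; bulk records (no cell_id)
    become single-member bundles keyed by a cell_id synthesized from the
    sequence_id. Every input record lands in a bundle or the reject list.
    """
    by_cell: dict[str, list[Rearrangement]] = {}
    for rec in records:
        key = rec.cell_id if rec.cell_id else f"bulk_{rec.sequence_id}"
        by_cell.setdefault(key, []).append(rec)

    bundles: list[CellBundle] = []
    rejected: list[Rearrangement] = []
    for cell_id, recs in by_cell.items():
        heavies = [r for r in recs if r.is_heavy]
        lights = [r for r in recs if not r.is_heavy]
        if len(heavies) != 1:
            rejected.extend(recs)
            continue
        bundles.append(CellBundle(cell_id=cell_id, heavy=heavies[0], lights=tuple(lights)))
    return bundles, rejected


# -- Newick -----------------------------------------------------------------

def read_newick(path_or_string, germline_label: str = GERMLINE_LABEL) -> PhyloTree:
    """Parse a Newick tree (file path or literal string) into a PhyloTree."""
    text = str(path_or_string)
    if not text.strip().startswith("(") and not text.strip().endswith(";"):
        with open(path_or_string) as handle:
            text = handle.read()
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=False,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"malformed Newick: {exc}") from exc

    def convert(dnode) -> Node:
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        node = Node(label=label, length=dnode.edge.length)
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        return node

    root = convert(dtree.seed_node)
    root.length = root.length  # dendropy may carry a root edge; keep as-is
    return PhyloTree(root)


def write_newick(tree: PhyloTree, path) -> None:
    with open(path, "w") as handle:
        handle.write(tree.to_newick() + "\n")


def write_fasta(sequences: dict[str, str], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")
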