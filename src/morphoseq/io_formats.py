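"""Readers and writers for the standard formats the pipeline touches:
TPS landmark files, FASTA / aligned FASTA, Newick trees, sidecar group
tables, and the plain-text diagnostic-rule config.

TPS dialect notes: records begin with ``LM=<k>`` (case-insensitive),
followed by k lines of two whitespace-separated numbers; ``ID=`` and
``IMAGE=`` lines are honoured for specimen naming and ``SCALE=`` lines are
ignored (coordinates are used as-is — Procrustes superimposition removes
scale anyway). Group labels are attached from an explicit two-column
sidecar table rather than parsed out of IMAGE paths.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord
from skbio import TreeNode

from .morphometry import LandmarkConfiguration, ShapeDataset
from .rules import RuleConfig, read_rules  # noqa: F401  (re-exported)

_VALID_RESIDUES = set("ACGTN-")
_IUPAC_AMBIG = set("RYSWKMBDHV")


@dataclass
class SequenceRecord:
    """One DNA sequence with its sample of origin.

    ``sample_code`` identifies the population sample (e.g. B1Ube, MxTap);
    ``accession`` is an optional database identifier.
    """

    seq_id: str
    residues: str
    sample_code: str | None = None
    accession: str | None = None

    def __post_init__(self) -> None:
        res = self.residues.upper().replace("U", "T")
        res = "".join("N" if c in _IUPAC_AMBIG else c for c in res)
        if not res:
            raise ValueError(f"empty sequence {self.seq_id!r}")
        bad = set(res) - _VALID_RESIDUES
        if bad:
            raise ValueError(f"{self.seq_id!r}: invalid residues {sorted(bad)}")
        self.residues = res

    def __len__(self) -> int:
        return len(self.residues)

    def reverse_complement(self) -> "SequenceRecord":
        comp = str(Seq(self.residues).reverse_complement())
        return SequenceRecord(self.seq_id, comp, self.sample_code, self.accession)


# ---------------------------------------------------------------------------
# TPS landmark files


_LM_RE = re.compile(r"^lm\s*=\s*(\S+)\s*$", re.IGNORECASE)
_KV_RE = re.compile(r"^(id|image|scale)\s*=\s*(.*)$", re.IGNORECASE)


def read_tps(path: str | Path) -> ShapeDataset:
    """Read a TPS landmark file into a ShapeDataset.

    One LandmarkConfiguration per ``LM=`` record, coordinate order
    preserved. Raises on malformed count lines, missing coordinate lines,
    or inconsistent landmark counts across specimens.
    """
    lines = Path(path).read_text().splitlines()
    configs: list[LandmarkConfiguration] = []
    i = 0
    record_no = 0
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line:
            continue
        m = _LM_RE.match(line)
        if not m:
            raise ValueError(f"{path}: expected LM=<k> record header, got {line!r}")
        try:
            k = int(m.group(1))
        except ValueError:
            raise ValueError(f"{path}: malformed landmark count {m.group(1)!r}") from None
        if k < 3:
            raise ValueError(f"{path}: LM={k}; need at least 3 landmarks")
        coords = np.empty((k, 2))
        for j in range(k):
            while i < len(lines) and not lines[i].strip():
                i += 1
            if i >= len(lines) or _LM_RE.match(lines[i].strip()) or _KV_RE.match(lines[i].strip()):
                raise ValueError(
                    f"{path}: record {record_no}: LM={k} declared but only {j} coordinate "
                    "lines found"
                )
            parts = lines[i].split()
            if len(parts) != 2:
                raise ValueError(f"{path}: bad coordinate line {lines[i]!r}")
            coords[j] = [float(parts[0]), float(parts[1])]
            i += 1
        record_no += 1
        specimen_id = f"specimen_{record_no}"
        while i < len(lines):
            nxt = lines[i].strip()
            if not nxt:
                i += 1
                continue
            kv = _KV_RE.match(nxt)
            if not kv:
                break
            key = kv.group(1).lower()
            if key == "id":
                specimen_id = kv.group(2).strip()
            # IMAGE and SCALE are noted but unused
            i += 1
        configs.append(LandmarkConfiguration(specimen_id=specimen_id, landmarks=coords))
    return ShapeDataset(configurations=configs)


def write_tps(dataset: ShapeDataset, path: str | Path) -> None:
    out = []
    for c in dataset.configurations:
        out.append(f"LM={c.k}")
        for x, y in c.landmarks:
            out.append(f"{x:.10g} {y:.10g}")
        out.append(f"ID={c.specimen_id}")
    Path(path).write_text("\n".join(out) + ("\n" if out else ""))


def read_group_table(path: str | Path) -> dict[str, str]:
    """Two-column whitespace/tab table: specimen_id, group label."""
    mapping: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: expected two columns")
        mapping[parts[0]] = parts[1]
    return mapping


def write_group_table(mapping: dict[str, str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{k}\t{v}\n" for k, v in mapping.items()))


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, aligned: bool = False) -> list[SequenceRecord]:
    """Read (aligned) FASTA; IDs must be unique; when ``aligned`` all
    records must have equal length."""
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord(seq_id=rec.id, residues=str(rec.seq)))
    if aligned and records:
        lengths = {len(r.residues) for r in records}
        if len(lengths) > 1:
            raise ValueError(f"{path}: aligned FASTA with unequal lengths {sorted(lengths)}")
    return records


def write_fasta(records: list[SequenceRecord], path: str | Path) -> None:
    bio = [_BioRecord(Seq(r.residues), id=r.seq_id, description="") for r in records]
    SeqIO.write(bio, str(path), "fasta-2line")


# ---------------------------------------------------------------------------
# Newick trees


def write_newick(tree: TreeNode, path: str | Path) -> None:
    """Write a tree with branch lengths; internal-node names (bootstrap
    supports) are preserved as internal labels."""
    tree.write(str(path), format="newick")


def read_newick(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path), format="newick", convert_underscores=False)


def node_support(node: TreeNode) -> float | None:
    """Bootstrap support parsed from an internal node label, if numeric."""
    if node.name is None:
        return None
    try:
        return float(node.name)
    except ValueError:
        return None
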