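"""Rule-based ITS1 sequence typing.

Raw amplicons are trimmed of their flanking rRNA gene fragments, collapsed
within a sample to the predominant sequence, mapped onto a fixed canonical
alignment coordinate system (columns 1..669) through a set of aligned
exemplars, and assigned to a named sequence type by evaluating diagnostic
markers (insertions, substitutions, reductions, tandem repeats) at stated
columns.

Marker matching tolerates one column of slack around insertion and repeat
ranges because published marker coordinates are routinely off by one
relative to any single alignment frame. Variant types inherit their
parent's required markers except where one of their own markers overlaps a
parent marker's range (the variant then *shadows* the parental marker —
e.g. an expansion that overwrites part of a parental diagnostic motif).
Classification is family-wise: a sequence belongs to a base-type family if
the base or any of its variants matches in full; the deepest full match
wins, and matching two different families raises the ambiguity flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq

from .io_formats import SequenceRecord
from .rules import Marker, RuleConfig


@dataclass
class AlignedSequence:
    """A sequence laid out on the canonical alignment columns 1..L."""

    seq_id: str
    columns: str  # residue or '-' per column
    source: SequenceRecord | None = None

    def __post_init__(self) -> None:
        if not self.columns:
            raise ValueError("empty column string")

    @property
    def length(self) -> int:
        return len(self.columns)

    def ungapped(self) -> str:
        return self.columns.replace("-", "")


@dataclass
class TypingResult:
    seq_id: str
    base_type: str  # type name or "unclassified"
    variant: str | None
    matched_markers: list[tuple[str, Marker]] = field(default_factory=list)
    unmatched_required: list[tuple[str, Marker]] = field(default_factory=list)
    ambiguous: bool = False

    @property
    def call(self) -> str:
        return self.variant or self.base_type


class FlankNotFoundError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Flank trimming


def _best_hamming(seq: str, motif: str, start: int = 0) -> tuple[int, int]:
    """(position, mismatches) of the minimum-Hamming occurrence of motif in
    seq[start:]; position is an index into seq."""
    best_pos, best_mm = -1, len(motif) + 1
    for i in range(start, len(seq) - len(motif) + 1):
        mm = sum(1 for a, b in zip(seq[i : i + len(motif)], motif) if a != b)
        if mm < best_mm:
            best_pos, best_mm = i, mm
            if mm == 0:
                break
    return best_pos, best_mm


def trim_flanks(
    record: SequenceRecord,
    flank5: str,
    flank3: str,
    max_mismatch: int = 2,
) -> SequenceRecord:
    """Return the subsequence strictly between the best matches of the 5'
    and 3' flanking-gene reference fragments.

    Each flank is located by a minimum-Hamming scan allowing up to
    ``max_mismatch`` mismatches; orientation is auto-detected by also
    scanning the reverse complement and keeping the better strand.
    """
    flank5, flank3 = flank5.upper(), flank3.upper()
    candidates = []
    for strand, seq in (("+", record.residues), ("-", str(Seq(record.residues).reverse_complement()))):
        p5, m5 = _best_hamming(seq, flank5)
        if p5 < 0:
            continue
        p3, m3 = _best_hamming(seq, flank3, start=p5 + len(flank5))
        if p3 < 0:
            continue
        candidates.append((m5 + m3, m5, m3, p5, p3, seq, strand))
    if not candidates:
        raise FlankNotFoundError("sequence too short to contain both flanks")
    total, m5, m3, p5, p3, seq, strand = min(candidates, key=lambda c: c[0])
    if m5 > max_mismatch:
        raise FlankNotFoundError(
            f"5' flank not found within {max_mismatch} mismatches (best: {m5})"
        )
    if m3 > max_mismatch:
        raise FlankNotFoundError(
            f"3' flank not found within {max_mismatch} mismatches (best: {m3})"
        )
    core = seq[p5 + len(flank5) : p3]
    if not core:
        raise FlankNotFoundError("flanks are adjacent; empty core")
    return SequenceRecord(record.seq_id, core, record.sample_code, record.accession)


# ---------------------------------------------------------------------------
# Predominant-sequence collapse


def _identity_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -1
    return aligner


def pairwise_identity(a: str, b: str, aligner: PairwiseAligner | None = None) -> float:
    """Fraction of identical residues over aligned ungapped column pairs of
    a global pairwise alignment."""
    aligner = aligner or _identity_aligner()
    aln = aligner.align(a, b)[0]
    blocks_a, blocks_b = aln.aligned
    matches = 0
    total = 0
    for (sa, ea), (sb, _eb) in zip(blocks_a, blocks_b):
        seg_a = a[sa:ea]
        seg_b = b[sb : sb + (ea - sa)]
        matches += sum(1 for x, y in zip(seg_a, seg_b) if x == y)
        total += ea - sa
    return matches / total if total else 0.0


@dataclass
class ClusterReport:
    cluster_sizes: list[int]
    chosen_cluster: int
    representative_count: int
    frequency_tie: bool


def collapse_predominant(
    records: Sequence[SequenceRecord], threshold: float = 0.99
) -> tuple[SequenceRecord, ClusterReport]:
    """Collapse one sample's sequences to the predominant one.

    Sequences are clustered by single linkage at pairwise identity >=
    ``threshold`` (clones differing by one or two substitutions out of
    ~550 nt sit well above 99% identity); the most frequent exact sequence
    of the largest cluster is returned. Frequency ties are resolved to the
    first sequence in input order and reported.
    """
    if not records:
        raise ValueError("no records to collapse")
    samples = {r.sample_code for r in records if r.sample_code is not None}
    if len(samples) > 1:
        raise ValueError(f"records from mixed samples: {sorted(samples)}")

    n = len(records)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    aligner = _identity_aligner()
    for i in range(n):
        for j in range(i + 1, n):
            if find(i) == find(j):
                continue
            if records[i].residues == records[j].residues or (
                pairwise_identity(records[i].residues, records[j].residues, aligner) >= threshold
            ):
                parent[find(j)] = find(i)

    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)
    ordered = sorted(clusters.values(), key=lambda ix: (-len(ix), min(ix)))
    chosen = ordered[0]

    counts: dict[str, int] = {}
    first_seen: dict[str, int] = {}
    for i in chosen:
        seq = records[i].residues
        counts[seq] = counts.get(seq, 0) + 1
        first_seen.setdefault(seq, i)
    best_count = max(counts.values())
    top = [s for s, c in counts.items() if c == best_count]
    winner = min(top, key=lambda s: first_seen[s])
    report = ClusterReport(
        cluster_sizes=[len(ix) for ix in ordered],
        chosen_cluster=0,
        representative_count=best_count,
        frequency_tie=len(top) > 1,
    )
    return records[first_seen[winner]], report


# ---------------------------------------------------------------------------
# Mapping to canonical alignment columns


def map_to_canonical(
    record: SequenceRecord,
    exemplars: Sequence[AlignedSequence],
    min_identity: float = 0.70,
) -> AlignedSequence:
    """Project a sequence onto the canonical columns through its nearest
    aligned exemplar.

    The query is globally aligned (match +1, mismatch -1, gap open -4, gap
    extend -1) against each exemplar's ungapped sequence; the best exemplar
    by identity carries the query through its own gap pattern into columns
    1..L. Query insertions relative to the exemplar have no canonical
    column and are dropped; columns the query does not cover are gaps.
    """
    if not exemplars:
        raise ValueError("no exemplars supplied")
    aligner = _identity_aligner()
    best = None
    for ex in exemplars:
        ident = pairwise_identity(ex.ungapped(), record.residues, aligner)
        if best is None or ident > best[0]:
            best = (ident, ex)
    ident, ex = best
    if ident < min_identity:
        raise ValueError(
            f"{record.seq_id!r}: best exemplar identity {ident:.2f} < {min_identity}; "
            "sequence is unlikely to be ITS1"
        )
    ex_ungapped = ex.ungapped()
    # residue index in the exemplar -> canonical column index (0-based)
    ex_cols = [i for i, c in enumerate(ex.columns) if c != "-"]
    aln = aligner.align(ex_ungapped, record.residues)[0]
    out = ["-"] * ex.length
    blocks_e, blocks_q = aln.aligned
    for (se, ee), (sq, _eq) in zip(blocks_e, blocks_q):
        for off in range(ee - se):
            out[ex_cols[se + off]] = record.residues[sq + off]
    return AlignedSequence(seq_id=record.seq_id, columns="".join(out), source=record)


# ---------------------------------------------------------------------------
# Marker evaluation and type classification


def _max_repeat_run(s: str, unit: str) -> int:
    best = 0
    for i in range(len(s)):
        c = 0
        j = i
        while s[j : j + len(unit)] == unit:
            c += 1
            j += len(unit)
        if c > best:
            best = c
    return best


def marker_present(marker: Marker, columns: str, L: int | None = None) -> bool:
    """Whether the marker's feature is present (ignoring required/forbidden
    polarity)."""
    L = L or len(columns)
    lo, hi = marker.window(L)
    window = columns[lo - 1 : hi]
    ungapped = window.replace("-", "")
    if marker.kind == "insertion":
        return marker.motif in ungapped
    if marker.kind == "substitution":
        seg = columns[marker.start - 1 : marker.start - 1 + len(marker.motif)]
        return seg == marker.motif
    if marker.kind == "reduction":
        return ungapped == marker.motif
    if marker.kind == "repeat":
        run = _max_repeat_run(ungapped, marker.motif)
        return (marker.n_min or 0) <= run <= (marker.n_max or run)
    raise ValueError(f"unknown marker kind {marker.kind!r}")


def _marker_excluded(marker: Marker, rules: RuleConfig) -> bool:
    return rules.is_excluded(marker.start) or rules.is_excluded(marker.end)


def _evaluate_type(
    name: str, columns: str, rules: RuleConfig
) -> tuple[bool, list[tuple[str, Marker]], list[tuple[str, Marker]]]:
    matched: list[tuple[str, Marker]] = []
    failed: list[tuple[str, Marker]] = []
    for m in rules.effective_markers(name):
        if _marker_excluded(m, rules):
            continue
        present = marker_present(m, columns, rules.alignment_length)
        ok = present if m.required else not present
        (matched if ok else failed).append((name, m))
    return (not failed), matched, failed


def classify_type(seq: AlignedSequence, rules: RuleConfig) -> TypingResult:
    """Assign a sequence to a base type and (optionally) variant.

    Every type's full marker set (own markers plus non-shadowed parental
    ones) is evaluated; a base family is matched if the base or any variant
    matches completely. The deepest full match within the matched family
    wins; two matched families set the ambiguity flag; no match yields
    "unclassified" together with the closest base type's missing markers.
    """
    if len(seq.columns) != rules.alignment_length:
        raise ValueError(
            f"sequence spans {len(seq.columns)} columns; rules expect {rules.alignment_length}"
        )
    evaluations = {}
    for t in rules.types.values():
        evaluations[t.name] = _evaluate_type(t.name, seq.columns, rules)

    def family(name: str) -> str:
        t = rules.types[name]
        return t.parent or t.name

    full = [name for name, (ok, _, _) in evaluations.items() if ok]
    families = []
    for name in full:
        f = family(name)
        if f not in families:
            families.append(f)
    ambiguous = len(families) >= 2

    if not full:
        # report the nearest base type's missing markers
        base_names = [t.name for t in rules.base_types()]
        best_base = max(
            base_names,
            key=lambda b: len(evaluations[b][1]) / max(1, len(evaluations[b][1]) + len(evaluations[b][2])),
        )
        _, matched, failed = evaluations[best_base]
        if not matched:
            matched, failed = [], []
        return TypingResult(
            seq_id=seq.seq_id,
            base_type="unclassified",
            variant=None,
            matched_markers=matched,
            unmatched_required=failed,
            ambiguous=False,
        )

    chosen_family = families[0]
    members = [n for n in full if family(n) == chosen_family]
    variants = [n for n in members if rules.types[n].parent is not None]
    if variants:
        # deepest match wins; among variants prefer the most specific
        chosen = max(
            variants,
            key=lambda n: (len(rules.effective_markers(n)), -list(rules.types).index(n)),
        )
        base, variant = chosen_family, chosen
    else:
        base, variant = chosen_family, None

    name = variant or base
    ok, matched, failed = evaluations[name]
    assert ok and not failed, "chosen type must match all its effective markers"
    return TypingResult(
        seq_id=seq.seq_id,
        base_type=base,
        variant=variant,
        matched_markers=matched,
        unmatched_required=[],
        ambiguous=ambiguous,
    )


def type_report(
    results: Sequence[TypingResult],
    sample_of: Mapping[str, str] | None = None,
    morphotype_of: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-sample summary: sequence count, type counts, and the modal
    (representative) type call; mirrors the usual survey-table layout."""
    rows: dict[str, list[TypingResult]] = {}
    for r in results:
        sample = (sample_of or {}).get(r.seq_id, r.seq_id)
        rows.setdefault(sample, []).append(r)
    out = []
    for sample, rs in rows.items():
        calls: dict[str, int] = {}
        first: dict[str, int] = {}
        for i, r in enumerate(rs):
            calls[r.call] = calls.get(r.call, 0) + 1
            first.setdefault(r.call, i)
        best = max(calls.values())
        rep = min((c for c, k in calls.items() if k == best), key=lambda c: first[c])
        row = {
            "sample": sample,
            "n": len(rs),
            "type_counts": ";".join(f"{t}:{c}" for t, c in sorted(calls.items())),
            "representative": rep,
        }
        if morphotype_of is not None:
            row["morphotype"] = morphotype_of.get(sample, "")
        out.append(row)
    return pd.DataFrame(out).set_index("sample") if out else pd.DataFrame(
        columns=["n", "type_counts", "representative"]
    )
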