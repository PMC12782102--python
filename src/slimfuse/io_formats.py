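"""Readers, writers and dataset bookkeeping for every on-disk format the
SLiM-prediction pipeline touches.

Formats handled here:

* FASTA protein sequences (via Biopython);
* motif interval labels, a TSV of ``seq_id<TAB>start<TAB>end`` with 1-based
  inclusive coordinates (intervals may overlap; the label track is their
  union);
* PSI-BLAST ``-out_ascii_pssm`` position-specific scoring matrices;
* AAindex1 flat files of per-amino-acid property indices;
* CD-HIT ``.clstr`` cluster listings;
* split-assignment TSVs (``seq_id<TAB>split``).

Coordinates are 1-based inclusive in files and 0-based half-open in memory;
conversion happens at the file boundary, nowhere else.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Canonical amino-acid order used throughout the package. It is the order of
#: the AAindex1 ``I`` header (A/L R/K N/M D/F C/P Q/S E/T G/W H/Y I/V read
#: column-wise) and also the column order PSI-BLAST prints.
AA_ORDER = "ARNDCQEGHILKMFPSTWYV"

#: Ambiguity codes accepted in input sequences; their feature handling is
#: mean-imputation (see the features module).
AMBIGUOUS = "XBZU"

VALID_LETTERS = frozenset(AA_ORDER + AMBIGUOUS)

SPLIT_NAMES = ("train", "validation", "test")


class FormatError(ValueError):
    """A file did not conform to the dialect this package expects."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ProteinRecord:
    """A protein sequence with an optional per-residue binary label track.

    ``labels[i] == 1`` marks residue ``i`` (0-based) as part of a short
    linear motif.
    """

    id: str
    seq: str
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"sequence {self.id!r} is empty")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int8)
            if self.labels.shape != (len(self.seq),):
                raise ValueError(
                    f"label track of {self.id!r} has length "
                    f"{len(self.labels)}, sequence has {len(self.seq)}"
                )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class PSSMProfile:
    """PSI-BLAST position-specific log-odds scores for one sequence.

    ``scores`` columns follow ``column_order`` exactly as printed in the
    source file; use :meth:`scores_canonical` for the package-wide order.
    """

    seq_id: str
    residues: str
    scores: np.ndarray  # L x 20, integer log-odds
    column_order: str

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValueError("PSSM scores must be L x 20")
        if len(self.residues) != self.scores.shape[0]:
            raise ValueError("residue string length != score row count")
        if sorted(self.column_order) != sorted(AA_ORDER):
            raise ValueError("column_order is not a permutation of the 20 letters")

    def scores_canonical(self) -> np.ndarray:
        """Scores with columns permuted into :data:`AA_ORDER`."""
        perm = [self.column_order.index(a) for a in AA_ORDER]
        return self.scores[:, perm]


@dataclass
class AAindexTable:
    """Ordered collection of AAindex1 property indices.

    Each accession maps to 20 values in :data:`AA_ORDER`; missing (``NA``)
    slots are flagged in ``na_masks`` and carry ``nan`` in ``entries``.
    """

    entries: dict[str, np.ndarray]
    na_masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for acc, vals in self.entries.items():
            vals = np.asarray(vals, dtype=float)
            if vals.shape != (20,):
                raise ValueError(f"accession {acc!r} does not have 20 values")
            self.entries[acc] = vals
            if acc not in self.na_masks:
                self.na_masks[acc] = np.isnan(vals)

    @property
    def accessions(self) -> list[str]:
        return list(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def values_imputed(self, accession: str) -> np.ndarray:
        """Property values with NA slots replaced by the mean of the rest."""
        vals = self.entries[accession].copy()
        mask = self.na_masks[accession]
        if mask.any():
            vals[mask] = vals[~mask].mean()
        return vals

    def scaled(self) -> "AAindexTable":
        """Min-max scale every accession to [0, 1] over its 20 values.

        NA slots are imputed first; constant entries map to 0.5.
        """
        out: dict[str, np.ndarray] = {}
        for acc in self.entries:
            vals = self.values_imputed(acc)
            span = vals.max() - vals.min()
            if span == 0:
                out[acc] = np.full(20, 0.5)
            else:
                out[acc] = (vals - vals.min()) / span
        return AAindexTable(out, {a: np.zeros(20, bool) for a in out})


@dataclass
class ClusterAssignment:
    """Partition of sequence ids into homology clusters (CD-HIT output)."""

    clusters: list[list[str]]
    representatives: list[str]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for group in self.clusters:
            for sid in group:
                if sid in seen:
                    raise ValueError(f"sequence id {sid!r} occurs in two clusters")
                seen.add(sid)
        if len(self.representatives) != len(self.clusters):
            raise ValueError("one representative required per cluster")

    @property
    def ids(self) -> list[str]:
        return [sid for group in self.clusters for sid in group]


@dataclass
class SplitAssignment:
    """Mapping of sequence id -> train / validation / test."""

    assignment: dict[str, str]
    seed: int

    def subset(self, records: list[ProteinRecord], split: str) -> list[ProteinRecord]:
        if split not in SPLIT_NAMES:
            raise ValueError(f"unknown split {split!r}")
        return [r for r in records if self.assignment.get(r.id) == split]


# ---------------------------------------------------------------------------
# FASTA and labels
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects.

    Sequences are uppercased and whitespace is stripped. Duplicate ids and
    empty files are format errors.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = re.sub(r"\s", "", str(rec.seq)).upper()
        records.append(ProteinRecord(id=rec.id, seq=seq))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: list[ProteinRecord], path: str | Path, width: int = 60) -> None:
    seqs = [SeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


def read_labels(path: str | Path, records: list[ProteinRecord]) -> list[ProteinRecord]:
    """Attach motif-interval labels to ``records``.

    The file holds ``seq_id<TAB>start<TAB>end`` rows with 1-based inclusive
    coordinates. Residues covered by at least one interval are labelled 1,
    all others 0; sequences absent from the file get an all-zero track.
    """
    by_id = {r.id: r for r in records}
    tracks = {r.id: np.zeros(len(r.seq), dtype=np.int8) for r in records}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 tab-separated fields")
            sid, start_s, end_s = parts
            if sid not in by_id:
                raise FormatError(f"{path}:{lineno}: unknown sequence id {sid!r}")
            start, end = int(start_s), int(end_s)
            L = len(by_id[sid].seq)
            if not (1 <= start <= end <= L):
                raise FormatError(
                    f"{path}:{lineno}: interval {start}-{end} out of range "
                    f"for {sid!r} (length {L})"
                )
            tracks[sid][start - 1 : end] = 1  # 1-based inclusive -> half-open
    return [replace(r, labels=tracks[r.id]) for r in records]


def write_labels(intervals: list[tuple[str, int, int]], path: str | Path) -> None:
    """Write 1-based inclusive motif intervals as a label TSV."""
    with open(path, "w") as fh:
        for sid, start, end in intervals:
            fh.write(f"{sid}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM
# ---------------------------------------------------------------------------

_PSSM_ROW = re.compile(r"^\s*(\d+)\s+([A-Z*])\s+(.*)$")


def read_ascii_pssm(path: str | Path, seq_id: str | None = None) -> PSSMProfile:
    """Parse a PSI-BLAST ``-out_ascii_pssm`` file.

    The first 20 numeric columns (log-odds) of each residue row are captured;
    the letter order is taken from the file's own column-header line, never
    assumed. ``seq_id`` defaults to the file stem.
    """
    path = Path(path)
    if seq_id is None:
        seq_id = path.stem
    lines = path.read_text().splitlines()

    header_idx = None
    column_order = None
    for i, line in enumerate(lines):
        letters = line.split()
        if len(letters) >= 20 and all(len(t) == 1 and t.isalpha() for t in letters):
            column_order = "".join(letters[:20])
            header_idx = i
            break
    if header_idx is None or column_order is None:
        raise FormatError(f"{path}: no PSSM column-header line found")

    residues: list[str] = []
    rows: list[list[int]] = []
    for lineno in range(header_idx + 1, len(lines)):
        line = lines[lineno]
        m = _PSSM_ROW.match(line)
        if m is None:
            break  # footer (lambda/K statistics) or blank line
        fields = m.group(3).split()
        numeric = []
        for tok in fields:
            try:
                numeric.append(float(tok))
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno + 1}: non-numeric field {tok!r} in PSSM row"
                ) from None
        if len(numeric) < 40:
            raise FormatError(
                f"{path}:{lineno + 1}: expected 40 numeric score fields, "
                f"got {len(numeric)}"
            )
        residues.append(m.group(2))
        rows.append([int(v) for v in numeric[:20]])
    if not rows:
        raise FormatError(f"{path}: PSSM contains no residue rows")
    return PSSMProfile(
        seq_id=seq_id,
        residues="".join(residues),
        scores=np.asarray(rows, dtype=np.int64),
        column_order=column_order,
    )


# ---------------------------------------------------------------------------
# AAindex1
# ---------------------------------------------------------------------------


def read_aaindex1(path: str | Path) -> AAindexTable:
    """Parse an AAindex1 flat file.

    Each entry starts with an ``H <accession>`` line; the ``I`` line is
    followed by two rows of 10 values whose column-wise reading gives the 20
    amino acids in :data:`AA_ORDER`. ``NA`` values are recorded in the NA
    mask and stored as ``nan``.
    """
    entries: dict[str, np.ndarray] = {}
    na_masks: dict[str, np.ndarray] = {}
    accession: str | None = None
    value_rows: list[list[float]] = []
    collecting = False

    def finish() -> None:
        nonlocal accession, value_rows, collecting
        if accession is None:
            return
        values = [v for row in value_rows for v in row]
        if len(values) != 20:
            raise FormatError(
                f"{path}: accession {accession!r} has {len(values)} values, expected 20"
            )
        arr = np.asarray(values, dtype=float)
        if accession in entries:
            raise FormatError(f"{path}: duplicate accession {accession!r}")
        entries[accession] = arr
        na_masks[accession] = np.isnan(arr)
        accession, value_rows, collecting = None, [], False

    with open(path) as fh:
        for line in fh:
            if line.startswith("H "):
                accession = line[2:].strip().split()[0]
                value_rows, collecting = [], False
            elif line.startswith("I ") or line.startswith("I\t"):
                collecting = True
            elif line.startswith("//"):
                finish()
            elif collecting and line[:1].isspace() and line.strip():
                row = [
                    float("nan") if tok.upper() == "NA" else float(tok)
                    for tok in line.split()
                ]
                value_rows.append(row)
            elif collecting and not line[:1].isspace():
                collecting = False
    if accession is not None:  # file missing final terminator
        finish()
    if not entries:
        raise FormatError(f"{path}: no AAindex entries found")
    return AAindexTable(entries, na_masks)


# ---------------------------------------------------------------------------
# CD-HIT clusters
# ---------------------------------------------------------------------------

_CLSTR_MEMBER = re.compile(
    r"^\d+\s+\d+(?:aa|nt),\s+>(?P<id>.*?)(?:\.\.\.)?\s+(?P<tail>\*|at\s+[0-9+./%-]+)\s*$"
)


def read_cdhit_clusters(path: str | Path) -> ClusterAssignment:
    """Parse a CD-HIT ``.clstr`` file into a :class:`ClusterAssignment`."""
    clusters: list[list[str]] = []
    representatives: list[str] = []
    current: list[str] | None = None
    current_rep: str | None = None

    def close() -> None:
        nonlocal current, current_rep
        if current is None:
            return
        if current_rep is None:
            raise FormatError(f"{path}: cluster {len(clusters)} has no '*' representative")
        clusters.append(current)
        representatives.append(current_rep)
        current, current_rep = None, None

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">Cluster"):
                close()
                current = []
            else:
                if current is None:
                    raise FormatError(f"{path}:{lineno}: member line before any cluster header")
                m = _CLSTR_MEMBER.match(line)
                if m is None:
                    raise FormatError(f"{path}:{lineno}: unparsable cluster member line")
                sid = m.group("id")
                current.append(sid)
                if m.group("tail") == "*":
                    current_rep = sid
    close()
    if not clusters:
        raise FormatError(f"{path}: no clusters found")
    return ClusterAssignment(clusters, representatives)


# ---------------------------------------------------------------------------
# splits and balancing
# ---------------------------------------------------------------------------


def assign_splits(
    clusters: ClusterAssignment,
    ratio: tuple[float, float, float] = (6, 2, 2),
    seed: int = 0,
) -> SplitAssignment:
    """Assign whole clusters to train/validation/test near a target ratio.

    Clusters are shuffled by ``seed``, ordered largest first (shuffle breaks
    size ties), and greedily placed in the split whose expected sequence
    count is furthest below target. All members of a cluster always share a
    split, preventing homology leakage between partitions.
    """
    if not clusters.clusters:
        raise ValueError("empty cluster set")
    ratio_arr = np.asarray(ratio, dtype=float)
    if ratio_arr.min() < 0 or ratio_arr.sum() <= 0:
        raise ValueError("ratio weights must be non-negative with positive sum")
    frac = ratio_arr / ratio_arr.sum()

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(clusters.clusters))
    groups = [clusters.clusters[i] for i in order]
    groups.sort(key=len, reverse=True)  # stable: shuffle decides among equals

    total = sum(len(g) for g in groups)
    target = frac * total
    counts = np.zeros(3)
    assignment: dict[str, str] = {}
    for group in groups:
        split = int(np.argmax(target - counts))
        counts[split] += len(group)
        for sid in group:
            assignment[sid] = SPLIT_NAMES[split]
    return SplitAssignment(assignment, seed)


def write_splits(splits: SplitAssignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, split in splits.assignment.items():
            fh.write(f"{sid}\t{split}\n")


def read_splits(path: str | Path, seed: int = -1) -> SplitAssignment:
    assignment: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2 or parts[1] not in SPLIT_NAMES:
                raise FormatError(f"{path}:{lineno}: expected 'seq_id<TAB>split'")
            assignment[parts[0]] = parts[1]
    return SplitAssignment(assignment, seed)


def downsample_negatives(
    records: list[ProteinRecord], seed: int = 0
) -> dict[str, np.ndarray]:
    """Class-balance training residues by down-sampling negatives.

    Returns, per sequence id, the sorted residue indices to include in the
    training loss: every motif residue plus ``min(#neg, #pos)`` uniformly
    sampled non-motif residues. Sequences themselves are never truncated —
    the selection only masks the loss, so attention still sees full context.
    """
    coords_pos: list[tuple[int, int]] = []
    coords_neg: list[tuple[int, int]] = []
    for ridx, rec in enumerate(records):
        if rec.labels is None:
            raise ValueError(f"record {rec.id!r} has no label track")
        for i in np.flatnonzero(rec.labels == 1):
            coords_pos.append((ridx, int(i)))
        for i in np.flatnonzero(rec.labels == 0):
            coords_neg.append((ridx, int(i)))
    if not coords_pos:
        raise ValueError("no positive residues to balance against")

    n_keep = min(len(coords_neg), len(coords_pos))
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(coords_neg), size=n_keep, replace=False) if n_keep else []
    kept = coords_pos + [coords_neg[i] for i in chosen]

    out: dict[str, list[int]] = {}
    for ridx, i in kept:
        out.setdefault(records[ridx].id, []).append(i)
    return {sid: np.asarray(sorted(ix), dtype=np.int64) for sid, ix in out.items()}
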