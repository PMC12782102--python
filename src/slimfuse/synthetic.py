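"""Synthetic benchmark generator with planted short linear motifs.

Every input the pipeline consumes — FASTA sequences, interval labels, CD-HIT
style cluster files, PSI-BLAST ASCII PSSMs, AAindex1 property tables and
per-residue embeddings — can be generated here with a controllable, planted
motif signal, so the full method is testable offline.

Signal model
------------
Motif segments are drawn from a residue composition biased toward a fixed set
of motif-preferred letters (P, L, D, E, S, T — the kinds of residues short
linear motifs are enriched in); background residues follow an average
protein composition. ``motif_signal_strength`` interpolates the motif
composition between background (0 = null, no signal anywhere) and the pure
preferred-letter distribution (1 = strong signal). The same strength scales
the extra conservation planted in motif PSSM columns and the embedding shift
applied to motif-preferred letters. Homology clusters are simulated by
copying each sequence with point mutations.

Everything written to disk uses exactly the dialects ``io_formats`` parses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .features import EmbeddingBackend
from .io_formats import (
    AA_ORDER,
    AAindexTable,
    ClusterAssignment,
    ProteinRecord,
    PSSMProfile,
    write_fasta,
    write_labels,
)

#: Letters over-represented inside planted motifs.
MOTIF_PREF = "PLDEST"

#: Average protein residue composition (rounded Swiss-Prot-like frequencies).
BACKGROUND_COMP = {
    "A": 0.083, "R": 0.055, "N": 0.040, "D": 0.055, "C": 0.014,
    "Q": 0.039, "E": 0.067, "G": 0.071, "H": 0.023, "I": 0.059,
    "L": 0.097, "K": 0.058, "M": 0.024, "F": 0.039, "P": 0.047,
    "S": 0.066, "T": 0.053, "W": 0.011, "Y": 0.029, "V": 0.069,
}


def _background_probs() -> np.ndarray:
    p = np.array([BACKGROUND_COMP[a] for a in AA_ORDER])
    return p / p.sum()


def _motif_probs(strength: float) -> np.ndarray:
    """Mixture between background and the uniform preferred-letter law."""
    pref = np.array([1.0 if a in MOTIF_PREF else 0.0 for a in AA_ORDER])
    pref /= pref.sum()
    m = float(np.clip(strength, 0.0, 1.0))
    return (1 - m) * _background_probs() + m * pref


@dataclass
class SynthConfig:
    """Study conditions for the synthetic benchmark.

    Defaults give ~100 sequences (50 clusters of 2 homologs) of 60–120
    residues with two planted motifs of 3–15 residues each — motif lengths
    matching the biological size range of short linear motifs — at full
    signal strength.
    """

    n_sequences: int = 50
    length_range: tuple[int, int] = (60, 120)
    motif_length_range: tuple[int, int] = (3, 15)
    motifs_per_sequence: int = 2
    motif_signal_strength: float = 1.0
    cluster_copies: int = 2
    mutation_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.mutation_rate <= 1:
            raise ValueError("mutation_rate must be in [0, 1]")
        if self.motif_length_range[1] > self.length_range[0]:
            raise ValueError(
                "largest motif length exceeds the shortest sequence length"
            )
        if self.cluster_copies < 1:
            raise ValueError("cluster_copies must be >= 1")


@dataclass
class SyntheticDataset:
    records: list[ProteinRecord]
    clusters: ClusterAssignment
    intervals: list[tuple[str, int, int]]  # 1-based inclusive, as written


# ---------------------------------------------------------------------------
# sequence generation
# ---------------------------------------------------------------------------


def _place_motifs(
    L: int, lengths: list[int], rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Sample non-overlapping half-open motif spans; greedy with retries."""
    spans: list[tuple[int, int]] = []
    for mlen in lengths:
        for _ in range(200):
            start = int(rng.integers(0, L - mlen + 1))
            span = (start, start + mlen)
            if all(span[1] <= s or span[0] >= e for s, e in spans):
                spans.append(span)
                break
        # if no free slot remains the motif is skipped; labels stay honest
    return sorted(spans)


def gen_proteins(cfg: SynthConfig) -> SyntheticDataset:
    """Generate labeled sequences grouped into mutation-copy homolog clusters."""
    rng = np.random.default_rng(cfg.seed)
    letters = np.array(list(AA_ORDER))
    bg_p = _background_probs()
    motif_p = _motif_probs(cfg.motif_signal_strength)

    records: list[ProteinRecord] = []
    groups: list[list[str]] = []
    reps: list[str] = []
    intervals: list[tuple[str, int, int]] = []

    for s in range(cfg.n_sequences):
        L = int(rng.integers(cfg.length_range[0], cfg.length_range[1] + 1))
        lengths = [
            int(rng.integers(cfg.motif_length_range[0], cfg.motif_length_range[1] + 1))
            for _ in range(cfg.motifs_per_sequence)
        ]
        spans = _place_motifs(L, lengths, rng)
        labels = np.zeros(L, dtype=np.int8)
        for a, b in spans:
            labels[a:b] = 1

        seq = np.where(
            labels == 1,
            rng.choice(letters, size=L, p=motif_p),
            rng.choice(letters, size=L, p=bg_p),
        )

        group: list[str] = []
        for c in range(cfg.cluster_copies):
            sid = f"syn{s:04d}" if c == 0 else f"syn{s:04d}_h{c}"
            variant = seq.copy()
            if c > 0 and cfg.mutation_rate > 0:
                mut = rng.random(L) < cfg.mutation_rate
                n_mut = int(mut.sum())
                if n_mut:
                    repl = np.where(
                        labels[mut] == 1,
                        rng.choice(letters, size=n_mut, p=motif_p),
                        rng.choice(letters, size=n_mut, p=bg_p),
                    )
                    variant[mut] = repl
            records.append(ProteinRecord(id=sid, seq="".join(variant), labels=labels.copy()))
            group.append(sid)
            for a, b in spans:
                intervals.append((sid, a + 1, b))  # to 1-based inclusive
        groups.append(group)
        reps.append(group[0])

    return SyntheticDataset(records, ClusterAssignment(groups, reps), intervals)


# ---------------------------------------------------------------------------
# ASCII PSSM generation
# ---------------------------------------------------------------------------

_PSSM_HEADER = (
    "Last position-specific scoring matrix computed, weighted observed "
    "percentages rounded down, information per position, and relative "
    "weight of gapless real matches to pseudocounts"
)


def write_ascii_pssm(profile: PSSMProfile, path: str | Path) -> None:
    """Write a profile in the PSI-BLAST ``-out_ascii_pssm`` dialect."""
    cols = list(profile.column_order)
    with open(path, "w") as fh:
        fh.write("\n")
        fh.write(_PSSM_HEADER + "\n")
        fh.write("           " + "  ".join(cols) + "   " + "  ".join(cols) + "\n")
        for i, (res, row) in enumerate(zip(profile.residues, profile.scores), 1):
            scores = " ".join(f"{int(v):3d}" for v in row)
            pct = " ".join(f"{0:3d}" for _ in row)
            fh.write(f"{i:5d} {res}  {scores}  {pct}  0.00 0.00\n")
        fh.write("\n")
        fh.write("                      K         Lambda\n")
        fh.write("Standard Ungapped    0.1347     0.3179\n")


def gen_pssms(
    records: list[ProteinRecord],
    cfg: SynthConfig,
    out_dir: str | Path | None = None,
) -> dict[str, PSSMProfile]:
    """Generate synthetic evolutionary profiles, conserved at motif positions.

    Every position gets small integer log-odds noise plus a bonus on its own
    residue's column; motif positions receive an extra self-residue
    conservation bonus scaled by the signal strength. With strength 0 the
    motif and background score distributions coincide.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    aa_index = {a: i for i, a in enumerate(AA_ORDER)}
    motif_bonus = int(round(4 * np.clip(cfg.motif_signal_strength, 0, 1)))
    profiles: dict[str, PSSMProfile] = {}
    for rec in records:
        if rec.labels is None:
            raise ValueError(f"record {rec.id!r} must be labeled")
        L = len(rec.seq)
        scores = rng.integers(-2, 3, size=(L, 20))
        for i, a in enumerate(rec.seq):
            j = aa_index.get(a)
            if j is None:
                continue
            scores[i, j] += 2
            if rec.labels[i] == 1:
                scores[i, j] += motif_bonus
        profiles[rec.id] = PSSMProfile(
            seq_id=rec.id, residues=rec.seq, scores=scores, column_order=AA_ORDER
        )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for sid, prof in profiles.items():
            write_ascii_pssm(prof, out_dir / f"{sid}.pssm")
    return profiles


# ---------------------------------------------------------------------------
# AAindex fixture generation
# ---------------------------------------------------------------------------

_AAINDEX_I_LINE = (
    "I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V"
)


def write_aaindex1(table: AAindexTable, path: str | Path) -> None:
    """Write a table in AAindex1 flat format (synthetic accessions)."""

    def fmt(v: float) -> str:
        return "NA" if np.isnan(v) else f"{v:7.3f}"

    with open(path, "w") as fh:
        for acc, vals in table.entries.items():
            fh.write(f"H {acc}\n")
            fh.write("D synthetic amino-acid property index\n")
            fh.write(_AAINDEX_I_LINE + "\n")
            fh.write("   " + " ".join(fmt(v) for v in vals[:10]) + "\n")
            fh.write("   " + " ".join(fmt(v) for v in vals[10:]) + "\n")
            fh.write("//\n")


def gen_aaindex_fixture(
    n_entries: int,
    n_informative: int,
    cfg: SynthConfig,
    path: str | Path | None = None,
) -> tuple[AAindexTable, list[str]]:
    """Build a synthetic AAindex table; returns (table, informative ids).

    Informative accessions track the motif-preferred letters: every one
    carries a baseline value of 0.5 on all preferred letters (so each is
    individually discriminative) plus a bonus of 0.5 on its own round-robin
    share of the preferred alphabet (so several together are strictly more
    informative than any one — complementary, not redundant). Non-informative accessions
    are random values *orthogonalized against the motif-composition
    contrast*, so under the null they carry exactly zero expected signal.
    """
    if n_informative > n_entries:
        raise ValueError("n_informative exceeds n_entries")
    rng = np.random.default_rng(cfg.seed + 2)
    pref = np.array([1.0 if a in MOTIF_PREF else 0.0 for a in AA_ORDER])
    contrast = pref / pref.sum() - _background_probs()
    pref_idx = np.flatnonzero(pref)
    n_groups = min(n_informative, len(pref_idx)) or 1

    entries: dict[str, np.ndarray] = {}
    informative: list[str] = []
    for i in range(n_entries):
        acc = f"SYN{i:04d}"
        if i < n_informative:
            vals = 0.5 * pref
            vals[pref_idx[np.arange(len(pref_idx)) % n_groups == i % n_groups]] += 0.5
            vals += rng.normal(0, 0.05, 20)
            informative.append(acc)
        else:
            vals = rng.normal(0, 1, 20)
            vals = vals - (vals @ contrast) / (contrast @ contrast) * contrast
        entries[acc] = vals
    table = AAindexTable(entries)
    if path is not None:
        write_aaindex1(table, path)
    return table, informative


# ---------------------------------------------------------------------------
# cluster file writing
# ---------------------------------------------------------------------------


def write_clstr(
    clusters: ClusterAssignment, records: list[ProteinRecord], path: str | Path
) -> None:
    """Write clusters in the CD-HIT ``.clstr`` dialect."""
    lengths = {r.id: len(r.seq) for r in records}
    with open(path, "w") as fh:
        for ci, (group, rep) in enumerate(
            zip(clusters.clusters, clusters.representatives)
        ):
            fh.write(f">Cluster {ci}\n")
            for mi, sid in enumerate(group):
                tail = "*" if sid == rep else "at 95.00%"
                fh.write(f"{mi}\t{lengths[sid]}aa, >{sid}... {tail}\n")


# ---------------------------------------------------------------------------
# embedding backend
# ---------------------------------------------------------------------------


class SyntheticEmbeddingBackend(EmbeddingBackend):
    """Deterministic pseudo-embedding backend.

    Each letter has a fixed pseudo-random base vector; a residue's embedding
    is its base vector mixed with the mean base vector of its +-2 neighbours
    (``context_weight``), plus a fixed shift vector on motif-preferred
    letters scaled by ``signal_strength``. The shift depends only on the
    sequence, never on labels, so no label information can leak into
    features; motif residues receive it in expectation because their
    composition is biased toward the preferred letters.
    """

    name = "synthetic"

    def __init__(
        self,
        dim: int = 1024,
        seed: int = 7,
        context_weight: float = 0.3,
        signal_strength: float = 1.0,
    ) -> None:
        if not 0 <= context_weight < 1:
            raise ValueError("context_weight must be in [0, 1)")
        self.dim = dim
        self.seed = seed
        self.context_weight = context_weight
        self.signal_strength = signal_strength
        letters = AA_ORDER + "XBZU"
        self._base = {
            a: np.random.default_rng([seed, ord(a)]).normal(0, 1, dim)
            for a in letters
        }
        self._shift = np.random.default_rng([seed, 10_007]).normal(0, 1, dim)

    def embed(self, seq: str) -> np.ndarray:
        unknown = set(seq) - set(self._base)
        if unknown:
            raise ValueError(f"unsupported residue letters {sorted(unknown)}")
        base = np.stack([self._base[a] for a in seq])
        L = len(seq)
        out = base.copy()
        if self.context_weight > 0 and L > 1:
            ctx = np.zeros_like(base)
            counts = np.zeros(L)
            for off in (-2, -1, 1, 2):
                lo, hi = max(0, -off), min(L, L - off)
                ctx[lo:hi] += base[lo + off : hi + off]
                counts[lo:hi] += 1
            out = (1 - self.context_weight) * base + self.context_weight * (
                ctx / counts[:, None]
            )
        if self.signal_strength:
            pref = np.array([a in MOTIF_PREF for a in seq], dtype=float)
            out = out + 0.8 * self.signal_strength * pref[:, None] * self._shift
        return out


# ---------------------------------------------------------------------------
# one-call dataset directory
# ---------------------------------------------------------------------------


def simulate_dataset(
    cfg: SynthConfig,
    out_dir: str | Path,
    n_aaindex: int = 60,
    n_informative: int = 8,
) -> dict:
    """Write a complete synthetic dataset directory and return its manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data = gen_proteins(cfg)
    write_fasta(data.records, out / "sequences.fasta")
    write_labels(data.intervals, out / "labels.tsv")
    write_clstr(data.clusters, data.records, out / "clusters.clstr")
    gen_pssms(data.records, cfg, out / "pssm")
    _, informative = gen_aaindex_fixture(
        n_aaindex, n_informative, cfg, out / "aaindex.txt"
    )
    manifest = {
        "n_sequences": len(data.records),
        "n_clusters": len(data.clusters.clusters),
        "n_motif_residues": int(sum(int(r.labels.sum()) for r in data.records)),
        "n_residues": int(sum(len(r) for r in data.records)),
        "aaindex_entries": n_aaindex,
        "aaindex_informative": informative,
        "config": {
            "n_sequences": cfg.n_sequences,
            "length_range": list(cfg.length_range),
            "motif_length_range": list(cfg.motif_length_range),
            "motifs_per_sequence": cfg.motifs_per_sequence,
            "motif_signal_strength": cfg.motif_signal_strength,
            "cluster_copies": cfg.cluster_copies,
            "mutation_rate": cfg.mutation_rate,
            "seed": cfg.seed,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
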