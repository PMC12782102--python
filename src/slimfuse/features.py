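"""Per-residue feature construction.

Three feature blocks feed the predictor:

* **seqfea** — semantic embeddings from a protein language-model backend,
  reduced to 128 dimensions with PCA fitted on training residues only;
* **phy** — physicochemical AAindex properties mapped per residue, smoothed
  twice with a centred sliding window, for two window lengths (7 and 11),
  giving 54 selected accessions x 2 windows = 108 channels;
* **pssm** — the 20 PSI-BLAST log-odds columns, standardized with
  training-set statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from .io_formats import AA_ORDER, AAindexTable, ProteinRecord, PSSMProfile

SOURCES = ("seqfea", "phy", "pssm", "fused")


@dataclass
class FeatureMatrix:
    """L x D block of named per-residue feature channels."""

    seq_id: str
    source: str
    values: np.ndarray
    channel_names: list[str]

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise ValueError(f"unknown feature source {self.source!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature values must be 2-D (residues x channels)")
        if len(self.channel_names) != self.values.shape[1]:
            raise ValueError("channel_names length != column count")

    @property
    def width(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# embedding backends
# ---------------------------------------------------------------------------


class EmbeddingBackend:
    """Contract for per-residue sequence embedders.

    An implementation maps a length-L sequence to an L x dim real matrix and
    is deterministic for a fixed instance.
    """

    name: str = "abstract"
    dim: int = 0

    def embed(self, seq: str) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class ProtBertBackend(EmbeddingBackend):
    """Adapter stub for a transformer protein language model.

    Requires externally provided weights and a deep-learning runtime; it is
    deliberately not bundled. Constructing it raises with instructions.
    """

    name = "protbert"
    dim = 1024

    def __init__(self) -> None:  # pragma: no cover - optional adapter
        raise RuntimeError(
            "the 'protbert' backend needs external pretrained weights; "
            "plug in your own EmbeddingBackend implementation or use the "
            "'synthetic' backend"
        )


def get_backend(name: str, **kwargs) -> EmbeddingBackend:
    """Look up an embedding backend by name (``synthetic`` or ``protbert``)."""
    if name == "synthetic":
        from .synthetic import SyntheticEmbeddingBackend

        return SyntheticEmbeddingBackend(**kwargs)
    if name == "protbert":
        return ProtBertBackend(**kwargs)
    raise ValueError(f"unknown embedding backend {name!r}")


def embed_sequences(
    backend: EmbeddingBackend, records: list[ProteinRecord]
) -> list[np.ndarray]:
    """Embed every record; errors are re-raised naming the offending id."""
    out = []
    for rec in records:
        try:
            mat = backend.embed(rec.seq)
        except Exception as exc:
            raise RuntimeError(f"embedding backend failed on {rec.id!r}: {exc}") from exc
        if mat.shape != (len(rec.seq), backend.dim):
            raise RuntimeError(
                f"backend returned shape {mat.shape} for {rec.id!r}, "
                f"expected {(len(rec.seq), backend.dim)}"
            )
        out.append(mat)
    return out


# ---------------------------------------------------------------------------
# PCA reduction of embeddings
# ---------------------------------------------------------------------------


@dataclass
class PCAModel:
    """Affine projection onto the top-k principal axes of training residues."""

    mean: np.ndarray
    components: np.ndarray  # k x dim, orthonormal rows
    explained_variance: np.ndarray

    @property
    def k(self) -> int:
        return self.components.shape[0]

    @property
    def dim(self) -> int:
        return self.components.shape[1]


def fit_pca(train_matrices: list[np.ndarray], k: int = 128) -> PCAModel:
    """Fit PCA on the pooled residue rows of the *training* sequences.

    Fitting on training data only keeps validation/test information out of
    the projection.
    """
    if not train_matrices:
        raise ValueError("no training matrices given")
    pooled = np.vstack(train_matrices)
    if pooled.shape[0] < k:
        raise ValueError(
            f"PCA needs at least k={k} pooled residue rows, got {pooled.shape[0]}"
        )
    model = PCA(n_components=k, svd_solver="full", random_state=0)
    model.fit(pooled)
    return PCAModel(
        mean=model.mean_.copy(),
        components=model.components_.copy(),
        explained_variance=model.explained_variance_.copy(),
    )


def apply_pca(model: PCAModel, matrix: np.ndarray, seq_id: str = "") -> FeatureMatrix:
    """Project an L x dim embedding to the L x k seqfea block."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[1] != model.dim:
        raise ValueError(
            f"matrix has {matrix.shape[1] if matrix.ndim == 2 else '?'} columns, "
            f"PCA model expects {model.dim}"
        )
    proj = (matrix - model.mean) @ model.components.T
    names = [f"pc{i + 1:03d}" for i in range(model.k)]
    return FeatureMatrix(seq_id=seq_id, source="seqfea", values=proj, channel_names=names)


# ---------------------------------------------------------------------------
# physicochemical (AAindex) block
# ---------------------------------------------------------------------------


@dataclass
class WindowSpec:
    """Centred sliding-window smoother: odd length N, applied ``passes`` times."""

    N: int
    passes: int = 2

    def __post_init__(self) -> None:
        if self.N < 1 or self.N % 2 == 0:
            raise ValueError(f"window length must be odd and >= 1, got {self.N}")
        if self.passes < 1:
            raise ValueError("passes must be >= 1")


def map_aaindex(
    seq: str, table: AAindexTable, accessions: list[str]
) -> np.ndarray:
    """Map a sequence onto AAindex property values, one column per accession.

    NA slots and ambiguity codes (X/B/Z/U) are imputed with the mean of the
    accession's defined values.
    """
    L = len(seq)
    out = np.empty((L, len(accessions)))
    aa_index = {a: i for i, a in enumerate(AA_ORDER)}
    for j, acc in enumerate(accessions):
        if acc not in table.entries:
            raise KeyError(f"accession {acc!r} not in AAindex table")
        vals = table.values_imputed(acc)
        fallback = vals.mean()
        col = np.array([vals[aa_index[a]] if a in aa_index else fallback for a in seq])
        out[:, j] = col
    return out


def window_average(matrix: np.ndarray, spec: WindowSpec) -> np.ndarray:
    """Smooth each column with a centred truncated-mean window.

    ``out[i]`` is the mean over rows ``j`` with ``|j - i| <= (N-1)/2`` that
    fall inside the sequence; windows shrink at the boundaries rather than
    padding. The pass is repeated ``spec.passes`` times.
    """
    mat = np.asarray(matrix, dtype=float)
    if mat.ndim == 1:
        mat = mat[:, None]
    L = mat.shape[0]
    half = (spec.N - 1) // 2
    idx = np.arange(L)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, L)
    counts = (hi - lo)[:, None]
    out = mat
    for _ in range(spec.passes):
        cs = np.vstack([np.zeros((1, out.shape[1])), np.cumsum(out, axis=0)])
        out = (cs[hi] - cs[lo]) / counts
    return out


def build_phyfea(
    seq: str,
    table: AAindexTable,
    selected: list[str],
    windows: tuple[WindowSpec, ...] = (WindowSpec(7), WindowSpec(11)),
    scale: bool = True,
    seq_id: str = "",
) -> FeatureMatrix:
    """Assemble the physicochemical block: map, smooth twice, concatenate.

    With the default 54 selected accessions and two windows the block is
    L x 108. ``scale`` min-max normalizes each accession over its 20 values
    first so heterogeneous property scales do not dominate.
    """
    if not selected:
        raise ValueError("no accessions selected")
    if not windows:
        raise ValueError("no windows given")
    src = table.scaled() if scale else table
    mapped = map_aaindex(seq, src, selected)
    blocks, names = [], []
    for w in windows:
        blocks.append(window_average(mapped, w))
        names.extend(f"{acc}|N{w.N}" for acc in selected)
    return FeatureMatrix(
        seq_id=seq_id, source="phy", values=np.hstack(blocks), channel_names=names
    )


# ---------------------------------------------------------------------------
# PSSM block
# ---------------------------------------------------------------------------


@dataclass
class PSSMNormalizer:
    """Per-column standardization statistics fitted on training profiles."""

    mean: np.ndarray
    std: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.std = np.asarray(self.std, dtype=float)
        if self.mean.shape != (20,) or self.std.shape != (20,):
            raise ValueError("normalizer statistics must have 20 entries")


def fit_pssm_normalizer(profiles: list[PSSMProfile]) -> PSSMNormalizer:
    """Pool training-profile rows (canonical column order) and fit mean/sd."""
    if not profiles:
        raise ValueError("no profiles to fit on")
    pooled = np.vstack([p.scores_canonical() for p in profiles]).astype(float)
    return PSSMNormalizer(mean=pooled.mean(axis=0), std=pooled.std(axis=0))


def build_pssm_features(
    profile: PSSMProfile, normalizer: PSSMNormalizer
) -> FeatureMatrix:
    """Standardize a profile into the L x 20 evolutionary block.

    Columns with zero training variance map to 0.
    """
    scores = profile.scores_canonical().astype(float)
    std = np.where(normalizer.std == 0, 1.0, normalizer.std)
    vals = (scores - normalizer.mean) / std
    vals[:, normalizer.std == 0] = 0.0
    names = [f"pssm_{a}" for a in AA_ORDER]
    return FeatureMatrix(
        seq_id=profile.seq_id, source="pssm", values=vals, channel_names=names
    )
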