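"""Sequence determinants of histone occupancy.

Normalized occupancy is modelled from local sequence with an
L1-penalized (LASSO) linear model over all mono- through
tetra-nucleotide counts (4 + 16 + 64 + 256 = 340 features) in a window
centered on each genomic position.  Window widths pair with footprint
size classes: 61 bp for the 60 bp class, 91 bp for 90, 121 bp for 120.
Models are trained on a contiguous prefix covering one sixth of the
genome and evaluated on the remainder, so train and test regions are
spatially disjoint.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LassoCV

from .genome_io import FragmentSet, GenomeSeq

__all__ = [
    "kmer_names",
    "kmer_features",
    "train_prefix_end",
    "contiguous_cv_splits",
    "SparseLinearModel",
    "fit_sparse",
    "evaluate",
    "read_internal_profile",
]

_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(_BASES)}
DEFAULT_KSET = (1, 2, 3, 4)
CLASS_WINDOW = {60: 61, 90: 91, 120: 121}   # size class -> k-mer window width


def kmer_names(k_set=DEFAULT_KSET) -> list[str]:
    """All k-mers for the given k values, in lexicographic order per k."""
    return [
        "".join(t) for k in k_set for t in itertools.product(_BASES, repeat=k)
    ]


def _encode(seq: str) -> np.ndarray:
    """Sequence to int codes; N (or any non-ACGT) encodes as -1."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(len(arr), -1, dtype=np.int64)
    for b, i in _CODE.items():
        out[arr == ord(b)] = i
    return out


def kmer_features(
    genome: GenomeSeq,
    contig: str,
    positions: np.ndarray,
    k_set=DEFAULT_KSET,
    window: int = 121,
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Count k-mers in the ``window`` bp centered at each position.

    Counting is on the forward strand, no reverse-complement collapsing.
    Windows containing N are excluded: the returned boolean mask marks
    the retained positions and the matrix has one row per retained
    position.  For fixed k the row sums equal window - k + 1.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    positions = np.asarray(positions, dtype=np.int64)
    seq = genome.contigs[contig]
    L = len(seq)
    half = window // 2
    circ = genome.circular.get(contig, True)
    if not circ and ((positions < half).any() or (positions + half >= L).any()):
        raise ValueError("positions within window/2 of a linear contig edge")
    code = _encode(seq)
    if circ:
        code = np.concatenate([code[-half:], code, code[: half + max(k_set)]])
        offset = half
    else:
        offset = 0
    names = kmer_names(k_set)
    n = len(positions)
    mats = []
    # a window is valid iff it contains no N anywhere in its span
    win_starts = positions - half + offset
    rel = np.arange(window)
    valid = ~np.any(code[win_starts[:, None] + rel] < 0, axis=1)
    idx = np.flatnonzero(valid)
    for k in k_set:
        # integer id of the k-mer starting at each genomic offset
        kid = np.zeros(len(code) - k + 1, dtype=np.int64)
        ok = np.ones(len(kid), dtype=bool)
        for j in range(k):
            c = code[j : j + len(kid)]
            kid = kid * 4 + np.where(c < 0, 0, c)
            ok &= c >= 0
        m = np.zeros((len(idx), 4**k), dtype=np.int32)
        starts = win_starts[idx]
        cols = kid[starts[:, None] + np.arange(window - k + 1)]
        rows = np.repeat(np.arange(len(idx)), window - k + 1)
        np.add.at(m, (rows, cols.ravel()), 1)
        mats.append(m)
    X = np.hstack(mats).astype(float)
    if (~valid).any():
        warnings.warn(f"{int((~valid).sum())} windows containing N were excluded")
    return X, names, valid


def train_prefix_end(genome_length: int, fraction: float = 1 / 6) -> int:
    """End (exclusive) of the contiguous training prefix: floor(L * fraction).

    For the 4,641,652 bp E. coli K-12 chromosome at fraction 1/6 this is
    position 773,608.
    """
    return int(genome_length * fraction)


def contiguous_cv_splits(n: int, n_folds: int = 10):
    """Contiguous-block CV splits, limiting spatial leakage between folds."""
    bounds = np.linspace(0, n, n_folds + 1).astype(int)
    idx = np.arange(n)
    for i in range(n_folds):
        test = idx[bounds[i] : bounds[i + 1]]
        train = np.concatenate([idx[: bounds[i]], idx[bounds[i + 1] :]])
        if len(test):
            yield train, test


@dataclass
class SparseLinearModel:
    """L1-penalized linear model of occupancy from k-mer counts.

    Coefficients are reported on the original count scale (features are
    standardized to unit variance internally for fitting).
    """

    coef: np.ndarray
    intercept: float
    alpha: float
    feature_names: list[str]
    train_region: tuple[int, int]
    response: str = "normalized_occupancy"

    def predict(self, X: np.ndarray) -> np.ndarray:
        return X @ self.coef + self.intercept

    def coefficients(self) -> pd.DataFrame:
        return pd.DataFrame({"feature": self.feature_names, "coefficient": self.coef})

    @property
    def n_nonzero(self) -> int:
        return int(np.sum(self.coef != 0))


def fit_sparse(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: list[str],
    train_region: tuple[int, int] = (0, 0),
    alphas: np.ndarray | None = None,
    n_folds: int = 10,
    log2_response: bool = False,
    random_state: int = 0,
) -> SparseLinearModel:
    """Fit the LASSO on training-region samples only.

    The penalty is selected by cross-validation over contiguous blocks
    within the training samples.  ``log2_response`` fits log2(y + eps)
    instead of raw normalized occupancy.
    """
    y = np.asarray(y, dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("constant response; nothing to fit")
    if log2_response:
        y = np.log2(y + 2 ** -8)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = X / sd
    cv = list(contiguous_cv_splits(len(y), n_folds))
    model = LassoCV(
        alphas=30 if alphas is None else alphas,
        cv=cv,
        max_iter=5000,
        random_state=random_state,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence chatter on tiny folds
        model.fit(Xs, y)
    return SparseLinearModel(
        coef=model.coef_ / sd,
        intercept=float(model.intercept_),
        alpha=float(model.alpha_),
        feature_names=list(feature_names),
        train_region=tuple(train_region),
        response="log2_occupancy" if log2_response else "normalized_occupancy",
    )


def _columnwise_spearman(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Spearman rho of each column of X against y (rank + Pearson)."""
    rx = np.apply_along_axis(stats.rankdata, 0, X)
    ry = stats.rankdata(y)
    rx = rx - rx.mean(axis=0)
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum(axis=0) * (ry**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        return (rx.T @ ry) / denom


def evaluate(
    model: SparseLinearModel,
    X: np.ndarray,
    y: np.ndarray,
    region: tuple[int, int],
    region_label: str = "test",
    top_n: int = 20,
) -> dict:
    """Model performance plus univariate k-mer informativeness.

    ``region`` must be disjoint from the model's training region unless
    the label is explicitly "train".  Reports Spearman rho of predicted
    vs observed, per-k-mer univariate Spearman correlations with the
    response, and the top/bottom ``top_n`` k-mers by that correlation.
    """
    t0, t1 = model.train_region
    r0, r1 = region
    if region_label != "train" and (r0 < t1 and r1 > t0):
        raise ValueError(
            f"evaluation region {region} overlaps training region {model.train_region}"
        )
    pred = model.predict(X)
    if np.ptp(pred) == 0 or np.ptp(y) == 0:
        rho, p = np.nan, np.nan
    else:
        rho, p = stats.spearmanr(pred, y)
    uni = _columnwise_spearman(X, np.asarray(y, dtype=float))
    ranking = (
        pd.DataFrame({"feature": model.feature_names, "rho": uni})
        .sort_values("rho", ascending=False)
        .reset_index(drop=True)
    )
    return {
        "region": region,
        "region_label": region_label,
        "rho": float(rho) if rho == rho else np.nan,
        "p_value": float(p) if p == p else np.nan,
        "univariate": ranking,
        "top": ranking.head(top_n),
        "bottom": ranking.tail(top_n).iloc[::-1].reset_index(drop=True),
        "n": len(y),
    }


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def read_internal_profile(
    fragments: FragmentSet,
    genome: GenomeSeq,
    exact_length: int,
    min_fragments: int = 100,
) -> dict:
    """Positional nucleotide enrichment inside fragments of one exact length.

    Only fragments of exactly ``exact_length`` bp contribute.  For each
    internal position p (1-based) and base b, enrichment
    E(p, b) = freq(p, b) / genome-wide freq(b), oriented on the genome
    forward strand.  The symmetry score is the mean over (p, b) of
    |E(p, b) - E(len + 1 - p, complement(b))|: 0 for a perfectly
    dyad-symmetric profile.  These profiles are internal to the
    protected fragment and therefore unaffected by nuclease cut bias.
    """
    df = fragments.df
    sel = df[(df["end"] - df["start"]) == exact_length]
    n = len(sel)
    if n == 0:
        warnings.warn(f"no fragments of exact length {exact_length}")
        return {"freq": pd.DataFrame(), "enrichment": pd.DataFrame(),
                "symmetry": np.nan, "n_fragments": 0}
    if n < min_fragments:
        warnings.warn(
            f"only {n} fragments of length {exact_length}; profile will be noisy"
        )
    counts = np.zeros((exact_length, 4))
    for contig, sub in sel.groupby("contig"):
        code = _encode(genome.contigs[contig])
        L = len(code)
        starts = sub["start"].to_numpy()
        idx = (starts[:, None] + np.arange(exact_length)) % L
        block = code[idx]
        for b in range(4):
            counts[:, b] += (block == b).sum(axis=0)
    freq = counts / counts.sum(axis=1, keepdims=True)
    bg = np.zeros(4)
    for contig, seq in genome.contigs.items():
        code = _encode(seq)
        for b in range(4):
            bg[b] += np.sum(code == b)
    bg /= bg.sum()
    enrich = freq / bg
    comp_idx = [ _CODE[b.translate(_COMPLEMENT)] for b in _BASES ]
    mirrored = enrich[::-1][:, comp_idx]
    symmetry = float(np.mean(np.abs(enrich - mirrored)))
    pos = pd.Index(np.arange(1, exact_length + 1), name="position")
    return {
        "freq": pd.DataFrame(freq, index=pos, columns=list(_BASES)),
        "enrichment": pd.DataFrame(enrich, index=pos, columns=list(_BASES)),
        "symmetry": symmetry,
        "n_fragments": n,
    }
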