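"""Intrinsic nucleosome occupancy scoring from sequence.

A 147-bp window (one nucleosome core) is summarized by the normalized
counts of all reverse-complement-collapsed k-mers for k = 1..4 plus its
GC fraction, and a Lasso linear model maps these features to an
occupancy value. Scoring a genome slides the window one bp at a time and
assigns the prediction to the central base (position 74 of 147). Because
the model is linear in k-mer counts, per-bp genome scoring reduces to
four sliding sums over per-position k-mer weights, so whole chromosomes
are scored in a handful of vectorized passes.

Feature symmetry: a k-mer and its reverse complement share one feature,
so the featurization (and therefore the score track, read in reverse) is
strand symmetric by construction.

The Lasso is fitted by cyclic coordinate descent with soft-thresholding
on internally standardized features; the standardization is folded back
into the stored weights so the model applies directly to raw features.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .genomic_io import GenomeSequence, ValidationError

WINDOW = 147
HALF = WINDOW // 2  # 73
KMAX = 4

_BASES = "ACGT"
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMP_TABLE = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP_TABLE)[::-1]


def encode(seq: str) -> np.ndarray:
    """Map a sequence to uint8 codes (A=0, C=1, G=2, T=3, N/other=4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _kmer_string(kid: int, k: int) -> str:
    s = []
    for _ in range(k):
        s.append(_BASES[kid % 4])
        kid //= 4
    return "".join(reversed(s))


def _build_feature_tables():
    """Per-k lookup from k-mer id to collapsed feature index, plus names.

    Features are ordered k = 1..4, canonical k-mer strings sorted within
    each k; the GC fraction is appended last.
    """
    names: list[str] = []
    tables: dict[int, np.ndarray] = {}
    offsets: dict[int, int] = {}
    for k in range(1, KMAX + 1):
        canon: dict[str, int] = {}
        ordered = []
        for kid in range(4 ** k):
            km = _kmer_string(kid, k)
            rc = revcomp(km)
            c = min(km, rc)
            if c not in canon:
                canon[c] = -1
                ordered.append(c)
        ordered.sort()
        offsets[k] = len(names)
        for c in ordered:
            canon[c] = len(names)
            names.append(f"{k}mer_{c}")
        table = np.empty(4 ** k, dtype=np.int64)
        for kid in range(4 ** k):
            km = _kmer_string(kid, k)
            table[kid] = canon[min(km, revcomp(km))]
        tables[k] = table
    names.append("gc_fraction")
    return tuple(names), tables, offsets


FEATURE_NAMES, _KMER_TABLE, _K_OFFSET = _build_feature_tables()
N_FEATURES = len(FEATURE_NAMES)  # 2 + 10 + 32 + 136 + 1 = 181


def _kmer_ids(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """k-mer ids at every start position, plus a validity mask (no N)."""
    n = len(codes) - k + 1
    ids = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        c = codes[j : j + n]
        ids = ids * 4 + np.minimum(c, 3)
        valid &= c < 4
    return ids, valid


def featurize_window(seq: str) -> np.ndarray:
    """Feature vector of one 147-bp window.

    Raises on wrong length; windows containing N are rejected because
    their k-mer counts are not comparable.
    """
    if len(seq) != WINDOW:
        raise ValidationError(f"window must be {WINDOW} bp, got {len(seq)}")
    codes = encode(seq)
    if np.any(codes >= 4):
        raise ValidationError("window contains N; excluded from featurization")
    return _featurize_codes(codes)


def _featurize_codes(codes: np.ndarray) -> np.ndarray:
    x = np.zeros(N_FEATURES)
    for k in range(1, KMAX + 1):
        ids, _ = _kmer_ids(codes, k)
        counts = np.bincount(_KMER_TABLE[k][ids], minlength=N_FEATURES)
        x += counts / len(ids)
    x[-1] = float(np.mean((codes == 1) | (codes == 2)))
    return x


@dataclass
class LassoModel:
    """Feature weights + intercept on the raw (unstandardized) feature scale."""

    feature_names: tuple[str, ...]
    weights: np.ndarray
    intercept: float
    lam: float
    n_train: int = 0
    seed: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.feature_names):
            raise ValidationError("weights/feature_names length mismatch")

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.weights + self.intercept

    def n_nonzero(self) -> int:
        return int(np.sum(self.weights != 0.0))

    def to_json(self, path: str | Path) -> None:
        obj = {
            "feature_names": list(self.feature_names),
            "weights": self.weights.tolist(),
            "intercept": self.intercept,
            "lambda": self.lam,
            "n_train": self.n_train,
            "seed": self.seed,
            "metadata": self.metadata,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "LassoModel":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            feature_names=tuple(obj["feature_names"]),
            weights=np.array(obj["weights"], dtype=float),
            intercept=float(obj["intercept"]),
            lam=float(obj["lambda"]),
            n_train=int(obj.get("n_train", 0)),
            seed=int(obj.get("seed", 0)),
            metadata=obj.get("metadata", {}),
        )


def fit_lasso(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    max_iter: int = 2000,
    tol: float = 1e-9,
    seed: int = 0,
    feature_names: Sequence[str] | None = None,
) -> LassoModel:
    """Cyclic coordinate descent for (1/2n)||y - Xw - b||^2 + lam * ||w||_1.

    Features are z-scored internally; the transform is folded back into
    the returned weights and intercept. The objective is checked to be
    non-increasing after every sweep. Deterministic for a fixed feature
    order; ``seed`` is recorded as provenance metadata.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValidationError("non-finite values in Lasso inputs")
    n, p = X.shape
    if n < 2:
        raise ValidationError("need at least 2 rows to fit")
    if lam < 0:
        raise ValidationError("lambda must be >= 0")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    active = sd > 0
    sd_safe = np.where(active, sd, 1.0)
    Xs = (X - mu) / sd_safe
    ybar = float(y.mean())
    yc = y - ybar

    w = np.zeros(p)
    r = yc.copy()  # residual y - Xs @ w
    col_sq = np.einsum("ij,ij->j", Xs, Xs) / n  # ~1 for active features

    def objective() -> float:
        return 0.5 * float(r @ r) / n + lam * float(np.abs(w).sum())

    prev_obj = objective()
    for _ in range(max_iter):
        max_delta = 0.0
        for j in range(p):
            if not active[j]:
                continue
            wj = w[j]
            rho = wj * col_sq[j] + float(Xs[:, j] @ r) / n
            wj_new = math.copysign(max(abs(rho) - lam, 0.0), rho) / col_sq[j]
            if wj_new != wj:
                r += Xs[:, j] * (wj - wj_new)
                w[j] = wj_new
                max_delta = max(max_delta, abs(wj_new - wj))
        obj = objective()
        if obj > prev_obj + 1e-10:
            raise RuntimeError("coordinate descent objective increased")
        prev_obj = obj
        if max_delta < tol:
            break

    weights = np.where(active, w / sd_safe, 0.0)
    intercept = ybar - float(weights @ mu)
    return LassoModel(
        feature_names=tuple(feature_names) if feature_names else FEATURE_NAMES[:p],
        weights=weights,
        intercept=intercept,
        lam=lam,
        n_train=n,
        seed=seed,
    )


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty at which every Lasso weight is exactly zero."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Xs = (X - mu) / sd
    yc = y - y.mean()
    return float(np.max(np.abs(Xs.T @ yc)) / len(y))


# ---------------------------------------------------------------------------
# Genome scoring
# ---------------------------------------------------------------------------

def _sliding_sum(x: np.ndarray, width: int, chunk: int = 1 << 20) -> np.ndarray:
    """Moving sum of ``width`` consecutive values, chunked to keep the
    cumulative-sum round-off error far below 1e-9."""
    n = len(x) - width + 1
    if n <= 0:
        return np.zeros(0)
    out = np.empty(n)
    start = 0
    while start < n:
        stop = min(start + chunk, n)
        seg = x[start : stop + width - 1]
        c = np.concatenate(([0.0], np.cumsum(seg)))
        out[start:stop] = c[width : width + (stop - start)] - c[: stop - start]
        start = stop
    return out


def score_inos(genome: GenomeSequence | str, model: LassoModel) -> np.ndarray:
    """Per-bp INOS track; NaN within 73 bp of either end and at every
    position whose 147-bp window contains an N.

    The track is exactly strand symmetric: it is the average of the
    forward sliding-sum pass and the reversed pass over the reverse
    complement, so summation order cannot break the symmetry that the
    collapsed feature set guarantees mathematically.
    """
    seq = genome.seq if isinstance(genome, GenomeSequence) else genome
    fwd = _score_one_strand(seq, model)
    rev = _score_one_strand(revcomp(seq), model)[::-1]
    return 0.5 * (fwd + rev)


def _score_one_strand(seq: str, model: LassoModel) -> np.ndarray:
    L = len(seq)
    if L < WINDOW:
        raise ValidationError(f"genome shorter than the {WINDOW}-bp window")
    if len(model.weights) != N_FEATURES:
        raise ValidationError("model does not match the packaged feature set")
    codes = encode(seq)

    n_windows = L - WINDOW + 1
    total = np.full(n_windows, model.intercept)
    for k in range(1, KMAX + 1):
        ids, valid = _kmer_ids(codes, k)
        wpos = model.weights[_KMER_TABLE[k][ids]]
        wpos[~valid] = 0.0  # N windows are masked below anyway
        total += _sliding_sum(wpos, WINDOW - k + 1) / (WINDOW - k + 1)
    gc_ind = ((codes == 1) | (codes == 2)).astype(float)
    total += model.weights[-1] * _sliding_sum(gc_ind, WINDOW) / WINDOW

    has_n = _sliding_sum((codes == 4).astype(float), WINDOW)
    total[has_n > 0] = np.nan

    scores = np.full(L, np.nan)
    scores[HALF : HALF + n_windows] = total
    return scores


def train_on_track(
    genome: GenomeSequence | str,
    track,
    sample_n: int = 5000,
    lam: float = 1e-3,
    seed: int = 0,
) -> LassoModel:
    """Fit a Lasso from sequence features to an occupancy track.

    Samples ``sample_n`` positions uniformly (seeded) among positions with
    a defined 147-bp window and a defined track value.
    """
    seq = genome.seq if isinstance(genome, GenomeSequence) else genome
    L = len(seq)
    codes = encode(seq)
    has_n = _sliding_sum((codes == 4).astype(float), WINDOW)
    centers = np.arange(HALF, L - HALF)
    defined = centers[has_n == 0]
    # restrict to the track span
    defined = defined[(defined >= track.offset) & (defined < track.end)]
    if sample_n > len(defined):
        raise ValidationError(
            f"sample_n {sample_n} exceeds {len(defined)} defined positions"
        )
    rng = np.random.default_rng(seed)
    sample = rng.choice(defined, size=sample_n, replace=False)
    sample.sort()
    X = np.empty((sample_n, N_FEATURES))
    for i, pos in enumerate(sample):
        X[i] = _featurize_codes(codes[pos - HALF : pos + HALF + 1])
    y = track.values[sample - track.offset]
    model = fit_lasso(X, y, lam=lam, seed=seed, feature_names=FEATURE_NAMES)
    model.metadata["trained_on"] = "occupancy_track"
    model.metadata["sample_n"] = sample_n
    return model


def default_model() -> LassoModel:
    """The packaged default model, trained on a synthetic GC-driven
    occupancy track (see the package data file's metadata)."""
    from importlib.resources import files

    path = files("hmrnuc").joinpath("data/default_inos_model.json")
    with path.open() as fh:
        obj = json.load(fh)
    return LassoModel(
        feature_names=tuple(obj["feature_names"]),
        weights=np.array(obj["weights"], dtype=float),
        intercept=float(obj["intercept"]),
        lam=float(obj["lambda"]),
        n_train=int(obj.get("n_train", 0)),
        seed=int(obj.get("seed", 0)),
        metadata=obj.get("metadata", {}),
    )
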