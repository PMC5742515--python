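"""Frame features: inter-channel IMF correlations and IMF statistics.

The discriminative signal for mental-task classification is taken to be the
*relationship between channels*: when a task stimulates one cortical region
more than others, the data recorded there decorrelates from the rest.  The
inter-IMFCC feature captures this as the Pearson correlation coefficient
between the same-order IMFs of two channels,

    R(i, j) = C(i, j) / sqrt(C(i, i) C(j, j)),

with the covariances normalised by 1/(N-1).  Alongside, per-channel IMF
statistics (std, RMS, entropy by default; eight further candidates are
available) describe each channel on its own.  For L IMFs, N_c channels and
a pair scheme resolving to P pairs the frame feature vector has dimension
L * (P + n_stats * N_c); with the defaults (L=3, all 15 pairs of the
six-channel montage, three statistics) that is 3 * (15 + 18) = 99.

Two deliberate normalisation quirks are preserved from the method's
definition: the feature ``std`` uses the population 1/N form while the
correlation covariance uses 1/(N-1); each lives in its own function.

Entropy needs discrete symbols.  Raw IMF samples are continuous, so they
are first quantized onto a uniform amplitude grid spanning the sequence's
min-max range -- 2**12 levels by default, mirroring the 12-bit acquisition
of the original recordings.  The grid size is configurable and recorded in
the feature provenance.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .emd import SiftConfig, decompose_frame
from .io import Frame

DEFAULT_STATS = ("std", "rms", "ent")
EXTRA_STAT_NAMES = ("avg", "med", "mod", "max", "min", "skew", "kurt")
DEFAULT_QUANT_LEVELS = 4096  # 12-bit amplitude grid

_REGIONS = {"C": "central", "P": "parietal", "O": "occipital"}


# ---------------------------------------------------------------------------
# Inter-channel IMF correlation
# ---------------------------------------------------------------------------

def inter_imfcc(u_i: np.ndarray, u_j: np.ndarray) -> float:
    """Correlation coefficient between same-order IMFs of two channels.

    Bounded in [-1, 1]; exactly 1 for identical inputs, 0 for unrelated
    ones.  Constant inputs have no defined correlation and raise rather
    than silently contributing zeros to the feature matrix.
    """
    u_i = np.asarray(u_i, dtype=float)
    u_j = np.asarray(u_j, dtype=float)
    if u_i.shape != u_j.shape or u_i.ndim != 1:
        raise ValueError("IMF sequences must be 1-D and of equal length")
    if u_i.size < 2:
        raise ValueError("need at least 2 samples")
    di = u_i - u_i.mean()
    dj = u_j - u_j.mean()
    denom = np.sqrt(np.dot(di, di) * np.dot(dj, dj))
    if denom == 0:
        raise ValueError("constant IMF has undefined correlation")
    r = float(np.dot(di, dj) / denom)
    return min(1.0, max(-1.0, r))


# ---------------------------------------------------------------------------
# Per-IMF statistics
# ---------------------------------------------------------------------------

def rms(u: np.ndarray) -> float:
    """Root mean square, sqrt(mean(u^2))."""
    u = _as_seq(u)
    return float(np.sqrt(np.mean(u * u)))


def std(u: np.ndarray) -> float:
    """Population standard deviation (1/N normalisation)."""
    u = _as_seq(u)
    return float(np.std(u))


def quantize(u: np.ndarray, levels: int = DEFAULT_QUANT_LEVELS) -> np.ndarray:
    """Map amplitudes onto integer levels of a uniform min-max grid."""
    u = _as_seq(u)
    lo, hi = float(u.min()), float(u.max())
    if hi == lo:
        return np.zeros(u.size, dtype=int)
    q = np.floor((u - lo) / (hi - lo) * levels).astype(int)
    return np.minimum(q, levels - 1)


def entropy(u: np.ndarray, levels: int = DEFAULT_QUANT_LEVELS) -> float:
    """Shannon entropy (bits) of the quantized amplitude distribution.

    Probabilities are occurrence counts n_r / N over the distinct quantized
    values; 0 log 0 terms contribute nothing.  Ranges over [0, log2 N].
    """
    q = quantize(u, levels)
    _, counts = np.unique(q, return_counts=True)
    p = counts / q.size
    return float(-np.sum(p * np.log2(p)))


def extra_stat(u: np.ndarray, name: str,
               levels: int = DEFAULT_QUANT_LEVELS) -> float:
    """One of the candidate statistics: avg, med, mod, max, min, skew, kurt.

    ``mod`` is the most frequent quantized amplitude (grid centre value),
    smallest on ties; ``kurt`` is non-excess kurtosis (a normal sequence
    gives 3).
    """
    u = _as_seq(u)
    if name == "avg":
        return float(np.mean(u))
    if name == "med":
        return float(np.median(u))
    if name == "max":
        return float(np.max(u))
    if name == "min":
        return float(np.min(u))
    if name == "mod":
        q = quantize(u, levels)
        values, counts = np.unique(q, return_counts=True)
        level = int(values[np.argmax(counts)])  # unique() sorts: ties -> smallest
        lo, hi = float(u.min()), float(u.max())
        if hi == lo:
            return lo
        return lo + (level + 0.5) * (hi - lo) / levels
    if name in ("skew", "kurt"):
        if u.size < 3:
            raise ValueError(f"{name} needs at least 3 samples")
        if name == "skew":
            return float(sstats.skew(u))
        return float(sstats.kurtosis(u, fisher=False))
    raise ValueError(f"unknown statistic {name!r}")


def _as_seq(u: np.ndarray) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    if u.size == 0:
        raise ValueError("empty input")
    return u.ravel()


def _stat_value(u: np.ndarray, name: str, levels: int) -> float:
    if name == "std":
        return std(u)
    if name == "rms":
        return rms(u)
    if name == "ent":
        return entropy(u, levels)
    return extra_stat(u, name, levels)


# ---------------------------------------------------------------------------
# Channel-pair schemes
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PairScheme:
    """Which channel pairs enter the inter-IMFCC features.

    ``all_pairs`` uses every unordered pair (15 for six channels);
    ``cross_hemisphere`` pairs each left-hemisphere channel with each
    right-hemisphere one (9); ``region_reference`` pairs both channels of a
    reference region with every channel outside it (8).
    """

    mode: str
    reference_region: str | None = None
    resolved_pairs: tuple[tuple[str, str], ...] = ()

    @property
    def n_pairs(self) -> int:
        return len(self.resolved_pairs)


def channel_region(label: str) -> str:
    letter = label[0].upper()
    if letter not in _REGIONS:
        raise ValueError(f"cannot infer region from channel label {label!r}")
    return _REGIONS[letter]


def channel_hemisphere(label: str) -> str:
    """Left for odd 10-20 indices, right for even."""
    digits = "".join(c for c in label if c.isdigit())
    if not digits:
        raise ValueError(f"cannot infer hemisphere from label {label!r}")
    return "left" if int(digits) % 2 == 1 else "right"


def resolve_pairs(
    channel_labels: Sequence[str],
    mode: str = "all_pairs",
    reference_region: str | None = None,
) -> PairScheme:
    """Resolve a pair-selection mode into an ordered list of label pairs."""
    labels = list(channel_labels)
    if mode == "all_pairs":
        pairs = tuple(itertools.combinations(labels, 2))
    elif mode == "cross_hemisphere":
        left = [c for c in labels if channel_hemisphere(c) == "left"]
        right = [c for c in labels if channel_hemisphere(c) == "right"]
        pairs = tuple((a, b) for a in left for b in right)
    elif mode == "region_reference":
        if reference_region not in _REGIONS.values():
            raise ValueError(
                "region_reference needs reference_region in "
                f"{sorted(_REGIONS.values())}, got {reference_region!r}"
            )
        ref = [c for c in labels if channel_region(c) == reference_region]
        rest = [c for c in labels if channel_region(c) != reference_region]
        pairs = tuple((a, b) for a in ref for b in rest)
    else:
        raise ValueError(f"unknown pair scheme {mode!r}")
    # dedupe unordered pairs, keep first occurrence
    seen, out = set(), []
    for a, b in pairs:
        key = frozenset((a, b))
        if a != b and key not in seen:
            seen.add(key)
            out.append((a, b))
    return PairScheme(mode=mode, reference_region=reference_region,
                      resolved_pairs=tuple(out))


# ---------------------------------------------------------------------------
# Feature assembly
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class FeatureMatrix:
    """Frames x features table with a name manifest and class labels."""

    values: np.ndarray
    feature_names: tuple[str, ...]
    labels: tuple[str, ...]
    provenance: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.feature_names = tuple(self.feature_names)
        self.labels = tuple(self.labels)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (frames x features)")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length != column count")
        if self.values.shape[0] != len(self.labels):
            raise ValueError("labels length != row count")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_csv(self, path: str | Path) -> Path:
        """CSV with the manifest as header plus a provenance sidecar JSON."""
        path = Path(path)
        df = pd.DataFrame(self.values, columns=list(self.feature_names))
        df.insert(0, "label", list(self.labels))
        df.to_csv(path, index=False)
        sidecar = path.with_suffix(path.suffix + ".json")
        with open(sidecar, "w") as fh:
            json.dump(self.provenance, fh, indent=2, default=str)
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        path = Path(path)
        df = pd.read_csv(path)
        sidecar = path.with_suffix(path.suffix + ".json")
        provenance = {}
        if sidecar.is_file():
            with open(sidecar) as fh:
                provenance = json.load(fh)
        return cls(
            values=df.drop(columns=["label"]).to_numpy(float),
            feature_names=tuple(df.columns[1:]),
            labels=tuple(df["label"].astype(str)),
            provenance=provenance,
        )


def feature_manifest(
    channel_labels: Sequence[str],
    scheme: PairScheme,
    stats: Sequence[str],
    n_imfs: int,
) -> tuple[str, ...]:
    """Deterministic column names: IMF-major, pairs before statistics."""
    names = []
    for m in range(1, n_imfs + 1):
        for a, b in scheme.resolved_pairs:
            names.append(f"imf{m}:cc:{a}-{b}")
        for stat in stats:
            for ch in channel_labels:
                names.append(f"imf{m}:{stat}:{ch}")
    return tuple(names)


def extract_features(
    frame: Frame,
    sift_config: SiftConfig | None = None,
    scheme: PairScheme | None = None,
    stats: Sequence[str] = DEFAULT_STATS,
    quant_levels: int = DEFAULT_QUANT_LEVELS,
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Feature row for one frame.

    Per IMF order m = 1..L: one inter-IMFCC per resolved channel pair, then
    one value per (statistic, channel).  A channel yielding fewer than L
    IMFs is an error -- padding would silently fabricate features.
    """
    sift_config = sift_config or SiftConfig()
    if scheme is None:
        scheme = resolve_pairs(frame.channel_labels, "all_pairs")
    known = set(DEFAULT_STATS) | set(EXTRA_STAT_NAMES)
    unknown = set(stats) - known
    if unknown:
        raise ValueError(f"unknown statistics: {sorted(unknown)}")

    imf_sets = decompose_frame(frame, sift_config)
    L = sift_config.max_imfs
    for ci, s in enumerate(imf_sets):
        if s.n_imfs < L:
            raise ValueError(
                f"channel {frame.channel_labels[ci]} produced {s.n_imfs} IMFs, "
                f"need {L}; frame too degenerate for this configuration"
            )
    ch_index = {lab: i for i, lab in enumerate(frame.channel_labels)}
    row = []
    for m in range(L):
        for a, b in scheme.resolved_pairs:
            row.append(inter_imfcc(imf_sets[ch_index[a]].imfs[m],
                                   imf_sets[ch_index[b]].imfs[m]))
        for stat in stats:
            for ch in frame.channel_labels:
                row.append(_stat_value(imf_sets[ch_index[ch]].imfs[m],
                                       stat, quant_levels))
    names = feature_manifest(frame.channel_labels, scheme, stats, L)
    return np.asarray(row, dtype=float), names


def extract_feature_matrix(
    frames: Sequence[Frame],
    sift_config: SiftConfig | None = None,
    scheme: PairScheme | None = None,
    stats: Sequence[str] = DEFAULT_STATS,
    quant_levels: int = DEFAULT_QUANT_LEVELS,
) -> FeatureMatrix:
    """Extract one feature row per frame into a :class:`FeatureMatrix`."""
    if not frames:
        raise ValueError("no frames given")
    sift_config = sift_config or SiftConfig()
    if scheme is None:
        scheme = resolve_pairs(frames[0].channel_labels, "all_pairs")
    rows, names = [], None
    for fr in frames:
        row, names = extract_features(fr, sift_config, scheme, stats,
                                      quant_levels)
        rows.append(row)
    return FeatureMatrix(
        values=np.vstack(rows),
        feature_names=names,
        labels=tuple(str(fr.task) for fr in frames),
        provenance={
            "extractor": "inter-imfcc",
            "n_imfs": sift_config.max_imfs,
            "sd_threshold": sift_config.sd_threshold,
            "scheme": scheme.mode,
            "reference_region": scheme.reference_region,
            "pairs": [list(p) for p in scheme.resolved_pairs],
            "stats": list(stats),
            "entropy_quant_levels": quant_levels,
        },
    )
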