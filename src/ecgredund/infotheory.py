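"""Binned entropy, mutual information, NMI and redundancy metrics.

Continuous channel amplitudes are discretized into fixed-width bins (default
0.5 mV, anchored at 0 mV) and every quantity is a plug-in (maximum
likelihood) estimate over the resulting empirical distributions:

* ``H(X) = -sum p(x) log p(x)`` — marginal and joint entropy, where joint
  distributions are over tuples of bin indices held in a sparse map of
  observed tuples (never a dense n-dimensional histogram).
* ``I(X;Y) = H(X) + H(Y) - H(X,Y)`` — mutual information.
* ``NMI(X;Y) = I(X;Y) / H(X,Y)`` — in [0,1]; 0 for independent channels,
  1 for identical channels.
* Channel redundancy ``R(X_i) = (H(X_i) - H(X_i | rest)) / H(X_i)`` — the
  fraction of a channel's information recoverable from the other channels.
* Set redundancy
  ``R(X_1..X_n) = (H(X_1..X_n) - sum_i H(X_i | rest)) / H(X_1..X_n)`` — the
  fraction of the joint information shared by at least two channels.

Conditional entropies are always obtained by the chain rule
``H(A|B) = H(A,B) - H(B)`` so a single sparse-histogram primitive serves
every formula.  NMI and both redundancy measures are ratios of entropies and
therefore independent of the logarithm base; entropies themselves default to
bits (base 2).

The plug-in estimator is biased upward for undersampled joints; the intended
mitigation is pooling many records (see :func:`ecgredund.records_io.concatenate`)
before estimating, which is how corpus-level redundancy figures are meant to
be produced.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ContractError, InternalConsistencyError, UndefinedValueError
from .records_io import MultichannelRecord

#: tolerance below which a negative plug-in MI is attributed to float round-off
_MI_CLAMP = 1e-12
#: tolerance for redundancy values straying outside [0,1]
_R_CLAMP = 1e-9


@dataclass(frozen=True)
class BinningConfig:
    """Fixed-width amplitude quantization.

    bin index = floor((value - anchor) / bin_width_mv); intervals are
    half-open ``[k*w, (k+1)*w)`` anchored at ``anchor`` (default 0 mV).
    """

    bin_width_mv: float = 0.5
    anchor: float = 0.0
    log_base: float = 2.0

    def __post_init__(self) -> None:
        if not self.bin_width_mv > 0:
            raise ContractError(f"bin_width_mv must be > 0, got {self.bin_width_mv}")
        if not self.log_base > 1:
            raise ContractError(f"log_base must be > 1, got {self.log_base}")


@dataclass(frozen=True)
class BinnedChannels:
    """Integer bin-index sequences per channel, plus the config that made them."""

    channel_names: tuple[str, ...]
    bins: np.ndarray  # (n_samples, n_channels) int64
    config: BinningConfig = field(default_factory=BinningConfig)

    def __post_init__(self) -> None:
        object.__setattr__(self, "channel_names", tuple(self.channel_names))
        bins = np.asarray(self.bins)
        if bins.ndim != 2 or bins.shape[1] != len(self.channel_names):
            raise ContractError("bins shape must be (n_samples, n_channels)")
        if not np.issubdtype(bins.dtype, np.integer):
            raise ContractError(f"bins must be integers, got dtype {bins.dtype}")
        object.__setattr__(self, "bins", bins)

    @property
    def n_samples(self) -> int:
        return self.bins.shape[0]

    @property
    def n_channels(self) -> int:
        return self.bins.shape[1]

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise ContractError(f"channel {name!r} not in {self.channel_names}") from None


@dataclass(frozen=True)
class RedundancyReport:
    """Per-channel and whole-set redundancy with provenance."""

    channel_names: tuple[str, ...]
    per_channel_R: tuple[float, ...]
    set_R: float
    config: BinningConfig
    n_samples: int

    def as_dict(self, percent: bool = False) -> dict:
        scale = 100.0 if percent else 1.0
        return {
            "channels": list(self.channel_names),
            "per_channel_R": [r * scale for r in self.per_channel_R],
            "set_R": self.set_R * scale,
            "bin_width_mv": self.config.bin_width_mv,
            "anchor_mv": self.config.anchor,
            "n_samples": self.n_samples,
            "scale": "percent" if percent else "fraction",
        }


def bin_record(record: MultichannelRecord, config: BinningConfig | None = None) -> BinnedChannels:
    """Quantize amplitudes into fixed-width bin indices (no clipping)."""
    config = config or BinningConfig()
    data = record.data
    if not np.isfinite(data).all():
        bad = np.argwhere(~np.isfinite(data))[0]
        raise ContractError(
            f"non-finite amplitude at sample {bad[0]}, channel "
            f"{record.channel_names[bad[1]]!r}"
        )
    bins = np.floor((data - config.anchor) / config.bin_width_mv).astype(np.int64)
    return BinnedChannels(record.channel_names, bins, config)


# ---------------------------------------------------------------------------
# Entropy primitives
# ---------------------------------------------------------------------------

def _entropy_from_counts(counts: np.ndarray, log_base: float) -> float:
    n = counts.sum()
    p = counts / n
    # 0*log0 := 0; counts from np.unique are strictly positive anyway
    return float(-(p * np.log(p)).sum() / math.log(log_base))


def _resolve_subset(channels: BinnedChannels, subset) -> np.ndarray:
    idx = np.atleast_1d(np.asarray(
        [channels.channel_index(s) if isinstance(s, str) else s for s in np.atleast_1d(subset)]
    )).astype(int)
    if idx.size == 0:
        raise ContractError("subset must be non-empty")
    if len(set(idx.tolist())) != idx.size:
        raise ContractError(f"duplicate channel indices in subset: {idx.tolist()}")
    if idx.min() < 0 or idx.max() >= channels.n_channels:
        raise ContractError(
            f"subset indices {idx.tolist()} out of range for {channels.n_channels} channels"
        )
    return idx


def entropy(channels: BinnedChannels, i: int | str) -> float:
    """Plug-in entropy of one binned channel, in units of ``log_base``."""
    idx = _resolve_subset(channels, [i])[0]
    col = channels.bins[:, idx]
    if col.size == 0:
        raise ContractError("cannot estimate entropy from an empty channel")
    _, counts = np.unique(col, return_counts=True)
    return _entropy_from_counts(counts, channels.config.log_base)


def joint_entropy(channels: BinnedChannels, subset: Sequence[int | str]) -> float:
    """Plug-in entropy of the joint bin-tuple distribution over ``subset``.

    Observed tuples are counted through a sparse unique-row pass; the
    distribution's support is the set of tuples actually seen, so memory is
    O(distinct tuples), never exponential in the subset size.
    """
    idx = _resolve_subset(channels, subset)
    sub = channels.bins[:, idx]
    if sub.shape[0] == 0:
        raise ContractError("cannot estimate entropy from an empty record")
    if idx.size == 1:
        _, counts = np.unique(sub[:, 0], return_counts=True)
    else:
        _, counts = np.unique(_tuple_codes(sub), return_counts=True)
    return _entropy_from_counts(counts, channels.config.log_base)


def _tuple_codes(sub: np.ndarray) -> np.ndarray:
    """Encode each row of bin indices as one integer key (mixed-radix pack).

    Distinct rows map to distinct codes, so counting codes counts tuples;
    packing into int64 is much faster than row-wise unique.  Falls back to
    structured row comparison if the combined radix would overflow."""
    lo = sub.min(axis=0)
    radix = sub.max(axis=0) - lo + 1
    if np.prod(radix, dtype=np.float64) < 2**62:
        codes = np.zeros(sub.shape[0], dtype=np.int64)
        for k in range(sub.shape[1]):
            codes = codes * int(radix[k]) + (sub[:, k] - lo[k])
        return codes
    return np.unique(sub, axis=0, return_inverse=True)[1]


def conditional_entropy(
    channels: BinnedChannels, target: Sequence[int | str], given: Sequence[int | str]
) -> float:
    """H(target | given) via the chain rule H(A|B) = H(A,B) - H(B)."""
    t = _resolve_subset(channels, target)
    g = _resolve_subset(channels, given)
    both = np.concatenate([t, g])
    if len(set(both.tolist())) != both.size:
        raise ContractError("target and given subsets overlap")
    return joint_entropy(channels, both.tolist()) - joint_entropy(channels, g.tolist())


def mutual_information(channels: BinnedChannels, i: int | str, j: int | str) -> float:
    """I(X_i; X_j) = H(X_i) + H(X_j) - H(X_i, X_j), clamped at tiny negatives.

    ``i == j`` is allowed and returns H(X_i)."""
    ii = _resolve_subset(channels, [i])[0]
    jj = _resolve_subset(channels, [j])[0]
    if ii == jj:
        return entropy(channels, int(ii))
    mi = (
        entropy(channels, int(ii))
        + entropy(channels, int(jj))
        - joint_entropy(channels, [int(ii), int(jj)])
    )
    if mi < 0:
        if mi < -_MI_CLAMP:
            raise InternalConsistencyError(f"plug-in MI = {mi} < -{_MI_CLAMP}")
        mi = 0.0
    return mi


def nmi(channels: BinnedChannels, i: int | str, j: int | str) -> float:
    """Normalized mutual information I(X;Y)/H(X,Y), in [0,1].

    Undefined (raises) when both channels are constant, since H(X,Y)=0."""
    ii = int(_resolve_subset(channels, [i])[0])
    jj = int(_resolve_subset(channels, [j])[0])
    h_joint = joint_entropy(channels, [ii, jj] if ii != jj else [ii])
    if h_joint <= 0.0:
        raise UndefinedValueError(
            f"NMI undefined: joint entropy of channels {ii} and {jj} is 0 (both constant)"
        )
    return mutual_information(channels, ii, jj) / h_joint


def nmi_matrix(channels: BinnedChannels) -> np.ndarray:
    """Symmetric matrix of pairwise NMI; diagonal is 1 for non-constant channels."""
    n = channels.n_channels
    out = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            try:
                out[i, j] = out[j, i] = nmi(channels, i, j)
            except UndefinedValueError as exc:
                raise UndefinedValueError(
                    f"NMI undefined for pair ({channels.channel_names[i]}, "
                    f"{channels.channel_names[j]}): {exc}"
                ) from None
    return out


# ---------------------------------------------------------------------------
# Redundancy
# ---------------------------------------------------------------------------

def _clamp_unit(value: float, what: str) -> float:
    if -_R_CLAMP < value < 0.0:
        return 0.0
    if 1.0 < value < 1.0 + _R_CLAMP:
        return 1.0
    if value < 0.0 or value > 1.0:
        raise InternalConsistencyError(f"{what} = {value} outside [0,1] beyond tolerance")
    return value


def channel_redundancy(channels: BinnedChannels, i: int | str) -> float:
    """Fraction of channel i's entropy recoverable from all other channels.

    R(X_i) = (H(X_i) - H(X_i | rest)) / H(X_i), with the conditional entropy
    computed as H(all) - H(all except i).
    """
    if channels.n_channels < 2:
        raise ContractError("channel redundancy needs at least 2 channels to condition on")
    ii = int(_resolve_subset(channels, [i])[0])
    h_i = entropy(channels, ii)
    if h_i <= 0.0:
        raise UndefinedValueError(
            f"channel redundancy undefined: channel {channels.channel_names[ii]!r} is constant"
        )
    everything = list(range(channels.n_channels))
    rest = [k for k in everything if k != ii]
    h_cond = joint_entropy(channels, everything) - joint_entropy(channels, rest)
    return _clamp_unit((h_i - h_cond) / h_i, f"R(X_{ii})")


def set_redundancy(channels: BinnedChannels, subset: Sequence[int | str] | None = None) -> float:
    """Fraction of the set's joint information shared by at least two channels.

    R(X_1..X_n) = (H(joint) - sum_i H(X_i | rest)) / H(joint); each
    conditional term is H(joint) - H(joint without channel i).  For a single
    channel the sum collapses to H(X_1) and R = 0 (nothing to share with).
    """
    if subset is None:
        subset = list(range(channels.n_channels))
    idx = _resolve_subset(channels, subset)
    h_joint = joint_entropy(channels, idx.tolist())
    if h_joint <= 0.0:
        raise UndefinedValueError("set redundancy undefined: all channels constant")
    if idx.size == 1:
        return 0.0
    cond_sum = 0.0
    for k in idx:
        rest = [int(m) for m in idx if m != k]
        cond_sum += h_joint - joint_entropy(channels, rest)
    return _clamp_unit((h_joint - cond_sum) / h_joint, "set R")


def redundancy_report(
    record: MultichannelRecord, config: BinningConfig | None = None
) -> RedundancyReport:
    """Bin a record and compute per-channel and whole-set redundancy."""
    config = config or BinningConfig()
    channels = bin_record(record, config)
    if channels.n_channels >= 2:
        per = tuple(channel_redundancy(channels, i) for i in range(channels.n_channels))
    else:
        per = (0.0,) * channels.n_channels
    return RedundancyReport(
        channel_names=record.channel_names,
        per_channel_R=per,
        set_R=set_redundancy(channels),
        config=config,
        n_samples=record.n_samples,
    )


def pcc(record: MultichannelRecord, i: int | str, j: int | str) -> float:
    """Sample Pearson correlation between two raw (unbinned) channels."""
    ii = record.channel_index(i) if isinstance(i, str) else int(i)
    jj = record.channel_index(j) if isinstance(j, str) else int(j)
    x = record.data[:, ii]
    y = record.data[:, jj]
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        name = record.channel_names[ii if np.std(x) == 0.0 else jj]
        raise UndefinedValueError(f"PCC undefined: channel {name!r} has zero variance")
    return float(np.corrcoef(x, y)[0, 1])
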