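"""Linear channel maps: limb-lead derivation, Dower/inverse-Dower, PCA,
and 15-channel redundancy augmentation.

All maps act sample-wise: an output record's row t is ``M @ input_row_t`` for
a fixed matrix M.  The inverse Dower transform (IDT) estimates the
3-channel vectorcardiogram (VCG) X/Y/Z from the 8 linearly independent
standard leads (I, II, V1-V6); the Dower forward matrix goes the other way
and is both the synthetic-lead generator's companion and the IDT's oracle.

Numerical convention for the IDT: the published Edenbrandt-Pahlm inverse is
the least-squares pseudoinverse of the Dower forward matrix rounded to three
decimals.  To make ``inverse_dower(dower_forward(v)) == v`` hold to machine
precision - a property the rounded table cannot deliver - the matrix applied
here is the full-precision Moore-Penrose pseudoinverse of the shipped
forward matrix; it agrees with the published table to ~1.5e-3 per entry
(both tables live in ``ecgredund/data/``).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from io import StringIO

import numpy as np
import pandas as pd

from .errors import ContractError, UndefinedValueError
from .records_io import MultichannelRecord, RecordCollection, concatenate
from .selection import INDEPENDENT_8_LEADS, STANDARD_12_LEADS

VCG_AXES = ("X", "Y", "Z")


@dataclass(frozen=True)
class TransformSpec:
    """A named linear map from input channels to output channels."""

    name: str
    input_channels: tuple[str, ...]
    output_channels: tuple[str, ...]
    matrix: np.ndarray  # (outputs, inputs)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.output_channels), len(self.input_channels)):
            raise ContractError(
                f"matrix shape {m.shape} does not match "
                f"{len(self.output_channels)} outputs x {len(self.input_channels)} inputs"
            )
        if not np.isfinite(m).all():
            raise ContractError("transform matrix has non-finite entries")
        object.__setattr__(self, "matrix", m)

    def apply(self, record: MultichannelRecord) -> MultichannelRecord:
        """Apply the map sample-wise; input channels are matched by name."""
        missing = [c for c in self.input_channels if c not in record.channel_names]
        if missing:
            raise ContractError(f"{self.name}: record is missing lead(s) {', '.join(missing)}")
        sub = record.subset(self.input_channels)
        out = sub.data @ self.matrix.T
        return MultichannelRecord(
            self.output_channels, out, record.sampling_rate_hz, label=record.label
        )


def _load_matrix_csv(name: str) -> pd.DataFrame:
    text = resources.files("ecgredund.data").joinpath(name).read_text()
    return pd.read_csv(StringIO(text), comment="#", index_col=0)


def _dower_forward_matrix() -> np.ndarray:
    """(8 leads x 3 axes) Dower forward matrix, rows in INDEPENDENT_8_LEADS order."""
    df = _load_matrix_csv("dower_forward.csv")
    return df.loc[list(_DOWER_LEAD_ORDER), list(VCG_AXES)].to_numpy(float)


_DOWER_LEAD_ORDER = ("V1", "V2", "V3", "V4", "V5", "V6", "I", "II")

_FORWARD = None
_INVERSE = None


def _matrices() -> tuple[np.ndarray, np.ndarray]:
    global _FORWARD, _INVERSE
    if _FORWARD is None:
        _FORWARD = _dower_forward_matrix()
        _INVERSE = np.linalg.pinv(_FORWARD)
    return _FORWARD, _INVERSE


def published_inverse_dower_matrix() -> np.ndarray:
    """The 3x8 inverse Dower table as printed (reference only)."""
    df = _load_matrix_csv("inverse_dower_published.csv")
    return df.loc[list(VCG_AXES), list(_DOWER_LEAD_ORDER)].to_numpy(float)


def dower_forward_spec() -> TransformSpec:
    fwd, _ = _matrices()
    return TransformSpec("dower_forward", VCG_AXES, _DOWER_LEAD_ORDER, fwd)


def inverse_dower_spec() -> TransformSpec:
    _, inv = _matrices()
    return TransformSpec("inverse_dower", _DOWER_LEAD_ORDER, VCG_AXES, inv)


def dower_forward(vcg: MultichannelRecord) -> MultichannelRecord:
    """Synthesize the 8 independent leads from a 3-channel VCG (X, Y, Z)."""
    missing = [a for a in VCG_AXES if a not in vcg.channel_names]
    if missing:
        raise ContractError(f"dower_forward: VCG record is missing axis(es) {', '.join(missing)}")
    return dower_forward_spec().apply(vcg)


def inverse_dower(record: MultichannelRecord) -> MultichannelRecord:
    """Estimate the VCG (X, Y, Z) from the 8 independent leads (IDT)."""
    return inverse_dower_spec().apply(record)


#: limb-lead derivation from leads I and II (Einthoven + Goldberger identities)
DERIVE_LIMB_SPEC = TransformSpec(
    "derive_limb_leads",
    ("I", "II"),
    ("I", "II", "III", "aVR", "aVL", "aVF"),
    np.array(
        [
            [1.0, 0.0],  # I
            [0.0, 1.0],  # II
            [-1.0, 1.0],  # III = II - I
            [-0.5, -0.5],  # aVR = -(I + II)/2
            [1.0, -0.5],  # aVL = I - II/2
            [-0.5, 1.0],  # aVF = II - I/2
        ]
    ),
)


def derive_limb_leads(record: MultichannelRecord) -> MultichannelRecord:
    """All six limb leads from leads I and II.

    III = II - I (Einthoven); aVR = -(I+II)/2, aVL = I - II/2,
    aVF = II - I/2 (Goldberger).  Their sums I + III - II and
    aVR + aVL + aVF vanish identically.
    """
    return DERIVE_LIMB_SPEC.apply(record)


def augment_15(record: MultichannelRecord) -> MultichannelRecord:
    """Append the IDT-estimated VCG to the 12 standard leads (15 channels).

    Adds three channels that are exact linear combinations of the existing
    ones, i.e. pure redundancy: the set redundancy of the 15-channel input
    can only stay equal or grow relative to the 12-lead original.
    """
    missing = [c for c in STANDARD_12_LEADS if c not in record.channel_names]
    if missing:
        raise ContractError(f"augment_15: record is missing lead(s) {', '.join(missing)}")
    base = record.subset(STANDARD_12_LEADS)
    vcg = inverse_dower(record)
    return MultichannelRecord(
        STANDARD_12_LEADS + VCG_AXES,
        np.hstack([base.data, vcg.data]),
        record.sampling_rate_hz,
        label=record.label,
    )


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PcaModel:
    """A corpus-wide PCA of the channel space.

    One transform is fit on the concatenation of all records and then applied
    to every record; per-record PCA is deliberately not offered, so each
    principal-component channel means the same thing across the corpus.
    """

    channel_names: tuple[str, ...]
    mean: np.ndarray  # (channels,), mV
    components: np.ndarray  # (components, channels), orthonormal rows
    explained_variance_fraction: np.ndarray  # non-increasing, sums to 1
    explained_variance: np.ndarray  # eigenvalues of the channel covariance

    def __post_init__(self) -> None:
        comp = np.asarray(self.components, float)
        gram = comp @ comp.T
        if not np.allclose(gram, np.eye(comp.shape[0]), atol=1e-8):
            raise ContractError("PCA components are not orthonormal to 1e-8")
        evf = np.asarray(self.explained_variance_fraction, float)
        if np.any(np.diff(evf) > 1e-12) or evf.min() < -1e-12 or evf.max() > 1 + 1e-12:
            raise ContractError("explained variance fractions must be non-increasing in [0,1]")

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def as_dict(self) -> dict:
        return {
            "channel_names": list(self.channel_names),
            "mean_mv": self.mean.tolist(),
            "components": self.components.tolist(),
            "explained_variance_fraction": self.explained_variance_fraction.tolist(),
        }


def pca_fit(corpus: RecordCollection | MultichannelRecord) -> PcaModel:
    """Fit PCA on the concatenated corpus channel covariance.

    Components are eigenvectors of the channel covariance ordered by
    non-increasing eigenvalue, with each component's sign fixed so its
    largest-magnitude loading is positive.
    """
    from sklearn.decomposition import PCA

    record = corpus if isinstance(corpus, MultichannelRecord) else concatenate(corpus)
    if record.n_samples <= record.n_channels:
        raise ContractError(
            f"PCA needs more samples ({record.n_samples}) than channels ({record.n_channels})"
        )
    if np.allclose(record.data.std(axis=0), 0.0):
        raise UndefinedValueError("PCA undefined: corpus has zero variance in every channel")
    pca = PCA(n_components=record.n_channels, svd_solver="full")
    pca.fit(record.data)
    comps = pca.components_.copy()
    for row in comps:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1.0
    return PcaModel(
        channel_names=record.channel_names,
        mean=pca.mean_,
        components=comps,
        explained_variance_fraction=pca.explained_variance_ratio_,
        explained_variance=pca.explained_variance_,
    )


def pca_transform(record: MultichannelRecord, model: PcaModel, q: int) -> MultichannelRecord:
    """Project a record onto the first q principal components (PC1..PCq)."""
    if not 1 <= q <= model.n_components:
        raise ContractError(f"q must be in [1, {model.n_components}], got {q}")
    missing = [c for c in model.channel_names if c not in record.channel_names]
    if missing:
        raise ContractError(f"pca_transform: record is missing channel(s) {', '.join(missing)}")
    sub = record.subset(model.channel_names)
    scores = (sub.data - model.mean) @ model.components[:q].T
    return MultichannelRecord(
        tuple(f"PC{i + 1}" for i in range(q)),
        scores,
        record.sampling_rate_hz,
        label=record.label,
    )
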