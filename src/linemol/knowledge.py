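"""Molecule-level "knowledge": descriptors + hashed topological fingerprint.

The knowledge node attached to each molecular line graph is initialised with
712 numbers: 200 molecular descriptors (physicochemical summaries such as
MolLogP, TPSA, QED) and a 512-bit hashed path-based topological fingerprint
(the RDKit fingerprint).  Descriptors live on wildly heterogeneous scales, so
before they are used — both as knowledge-node inputs and as regression targets
during pre-training — they are robust-standardised: per-descriptor median and
an interquartile-range-derived scale, z-scores clipped at ±10, non-finite
values imputed to 0.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem, DataStructs, RDLogger
from rdkit.Chem import Descriptors

from .molgraph import MolecularGraph, parse_smiles

__all__ = [
    "N_DESCRIPTORS",
    "N_FP_BITS",
    "KNOWLEDGE_DIM",
    "DESCRIPTOR_NAMES",
    "KnowledgeVector",
    "DescriptorNormalizer",
    "compute_descriptors",
    "compute_fingerprint",
    "fit_normalizer",
    "apply_normalizer",
    "build_knowledge_vector",
]

RDLogger.DisableLog("rdApp.*")

N_DESCRIPTORS = 200
N_FP_BITS = 512
KNOWLEDGE_DIM = N_DESCRIPTORS + N_FP_BITS

# First 200 entries of RDKit's descriptor registry, in registry order.  The
# names are frozen into every normalizer/checkpoint so a registry reordering
# in a future toolkit version is detectable.
_DESC_FUNCS = Descriptors._descList[:N_DESCRIPTORS]
DESCRIPTOR_NAMES = tuple(name for name, _ in _DESC_FUNCS)

# IQR of a standard normal; divides the IQR so the scale estimates sigma.
_NORMAL_IQR = 1.3489795003921634


@dataclass
class KnowledgeVector:
    """Assembled knowledge-node input: [descriptors(200), fingerprint(512)]."""

    descriptors: np.ndarray       # normalized, finite, length 200
    fingerprint: np.ndarray       # binary, length 512
    raw_descriptors: np.ndarray   # pre-normalization, may contain non-finite

    @property
    def vector(self) -> np.ndarray:
        return np.concatenate([self.descriptors, self.fingerprint.astype(float)])

    @property
    def dim(self) -> int:
        return self.descriptors.size + self.fingerprint.size


def _mol_of(g) -> Chem.Mol:
    # Re-parse from canonical SMILES so descriptors/fingerprints are bitwise
    # invariant to the input spelling (a few descriptors are sums whose
    # floating-point value depends on atom order).
    if isinstance(g, MolecularGraph):
        smiles = g.smiles_canonical
    elif isinstance(g, Chem.Mol):
        smiles = Chem.MolToSmiles(g)
    else:
        smiles = parse_smiles(str(g)).smiles_canonical
    return Chem.MolFromSmiles(smiles)


def compute_descriptors(g) -> np.ndarray:
    """200 raw molecular descriptors; failures become NaN, never exceptions."""
    mol = _mol_of(g)
    out = np.empty(N_DESCRIPTORS)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k, (_, fn) in enumerate(_DESC_FUNCS):
            try:
                out[k] = float(fn(mol))
            except Exception:
                out[k] = np.nan
    return out


def compute_fingerprint(g, n_bits: int = N_FP_BITS) -> np.ndarray:
    """Hashed path-based topological fingerprint folded to ``n_bits`` bits."""
    mol = _mol_of(g)
    fp = Chem.RDKFingerprint(mol, fpSize=n_bits)
    arr = np.zeros(n_bits, dtype=np.int8)
    DataStructs.ConvertToNumpyArray(fp, arr)
    return arr.astype(np.float64)


@dataclass
class DescriptorNormalizer:
    """Per-descriptor robust affine transform with clipping.

    z_k = clip((x_k - loc_k) / scale_k, -clip_bound, +clip_bound); non-finite
    inputs map to 0.  loc is the median over finite training values; scale is
    IQR / 1.3490 (consistent for sigma under normality), with degenerate
    (constant or all-missing) descriptors assigned scale 1.
    """

    loc: np.ndarray
    scale: np.ndarray
    clip_bound: float = 10.0
    n_fitted: int = 0
    names: tuple = field(default=DESCRIPTOR_NAMES)

    def __post_init__(self):
        self.loc = np.asarray(self.loc, dtype=float)
        self.scale = np.asarray(self.scale, dtype=float)
        if np.any(self.scale <= 0):
            raise ValueError("normalizer scales must be strictly positive")

    def to_json(self) -> str:
        return json.dumps(
            {
                "loc": self.loc.tolist(),
                "scale": self.scale.tolist(),
                "clip_bound": self.clip_bound,
                "n_fitted": self.n_fitted,
                "names": list(self.names),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "DescriptorNormalizer":
        d = json.loads(text)
        return cls(
            loc=np.array(d["loc"]),
            scale=np.array(d["scale"]),
            clip_bound=d["clip_bound"],
            n_fitted=d["n_fitted"],
            names=tuple(d["names"]),
        )


def fit_normalizer(corpus, clip_bound: float = 10.0) -> DescriptorNormalizer:
    """Fit robust location/scale per descriptor over the finite entries only."""
    mat = np.asarray(list(corpus), dtype=float)
    if mat.size == 0:
        raise ValueError("cannot fit a descriptor normalizer on an empty corpus")
    if mat.ndim != 2:
        raise ValueError("corpus must be a sequence of raw descriptor vectors")
    n, d = mat.shape
    loc = np.zeros(d)
    scale = np.ones(d)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k in range(d):
            col = mat[:, k]
            finite = col[np.isfinite(col)]
            if finite.size == 0:
                continue
            loc[k] = np.median(finite)
            q75, q25 = np.percentile(finite, [75, 25])
            s = (q75 - q25) / _NORMAL_IQR
            if s > 0:
                scale[k] = s
    return DescriptorNormalizer(loc=loc, scale=scale, clip_bound=clip_bound, n_fitted=n)


def apply_normalizer(nz: DescriptorNormalizer, raw: np.ndarray) -> np.ndarray:
    raw = np.asarray(raw, dtype=float)
    if raw.shape != nz.loc.shape:
        raise ValueError(f"raw descriptor vector has shape {raw.shape}, expected {nz.loc.shape}")
    with np.errstate(invalid="ignore"):
        z = (raw - nz.loc) / nz.scale
    z = np.clip(z, -nz.clip_bound, nz.clip_bound)
    z[~np.isfinite(raw)] = 0.0
    return z


def build_knowledge_vector(g, nz: DescriptorNormalizer) -> KnowledgeVector:
    """Descriptors (normalized) then fingerprint, assembled in that order."""
    raw = compute_descriptors(g)
    return KnowledgeVector(
        descriptors=apply_normalizer(nz, raw),
        fingerprint=compute_fingerprint(g),
        raw_descriptors=raw,
    )
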