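"""Engineered peptide descriptors and the integer encoding for the
embedding branch.

The manual feature vector has 35 components, in this fixed order:

====================  ====  =====================================================
block                 dim   meaning
====================  ====  =====================================================
``paac``               30   pseudo amino acid composition, 20 composition
                            components + lambda (default 10) sequence-order
                            correlation factors
``length``              1   number of residues
``shannon``             1   Shannon entropy of the residue distribution (nats)
``gravy``               1   grand average of hydropathy (Kyte-Doolittle)
``mol_weight``          1   average molecular weight, Daltons
``charge``              1   Henderson-Hasselbalch net charge at pH 10
====================  ====  =====================================================

Pseudo amino acid composition (PAAC) augments the 20 amino-acid frequencies
f_u with lambda "tier correlation" factors tau_k that retain sequence-order
information. With weight w, the components are

    p_u = f_u / (sum_i f_i + w * sum_k tau_k)           for u = 1..20
    p_u = w * tau_{u-20} / (sum_i f_i + w * sum_k tau_k)  for u = 21..20+lambda

where tau_k averages, over all residue pairs k positions apart, the squared
difference of three standardized physicochemical properties (hydrophobicity,
hydrophilicity, side-chain mass). All 20+lambda components are non-negative
and sum to one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import tables
from .io import LabeledDataset, validate_sequence
from .tables import AA_TO_INDEX, ALPHABET, INDEX_TO_AA

logger = logging.getLogger(__name__)

#: Column names of the 35-dimensional manual feature vector, in order.
FEATURE_NAMES: tuple[str, ...] = tuple(
    [f"paac_{aa}" for aa in ALPHABET]
    + [f"paac_tau{k}" for k in range(1, 11)]
    + ["length", "shannon_entropy", "gravy", "molecular_weight", "charge_ph10"]
)


def _normalize_scale(scale: dict[str, float]) -> np.ndarray:
    """Standardize a 20-value property table to mean 0, SD 1 (population)."""
    values = np.array([scale[aa] for aa in ALPHABET], dtype=float)
    return (values - values.mean()) / values.std()


@dataclass
class PAACParams:
    """Parameters of the pseudo amino acid composition.

    ``lam`` is the number of correlation tiers (must be < sequence length),
    ``w`` the weight of the correlation block relative to composition.
    The three property scales are standardized over the 20 residues before
    use unless ``normalize_scales`` is off; without standardization the
    side-chain mass term (tens of Daltons) would dominate the coupling.
    """

    lam: int = 10
    w: float = 0.05
    hydrophobicity: dict[str, float] = field(
        default_factory=lambda: dict(tables.KYTE_DOOLITTLE)
    )
    hydrophilicity: dict[str, float] = field(
        default_factory=lambda: dict(tables.HOPP_WOODS)
    )
    side_chain_mass: dict[str, float] = field(
        default_factory=lambda: dict(tables.SIDE_CHAIN_MASS)
    )
    normalize_scales: bool = True

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.w < 0:
            raise ValueError("w must be >= 0")

    def scale_matrix(self) -> np.ndarray:
        """3 x 20 matrix of the (optionally standardized) property scales,
        columns in alphabet order."""
        rows = [self.hydrophobicity, self.hydrophilicity, self.side_chain_mass]
        if self.normalize_scales:
            return np.stack([_normalize_scale(r) for r in rows])
        return np.stack(
            [np.array([r[aa] for aa in ALPHABET], dtype=float) for r in rows]
        )


@dataclass
class ChargeParams:
    """pH and pKa table for the net-charge feature (defaults: pH 10,
    EMBOSS-style pKa set)."""

    ph: float = 10.0
    pka_table: dict[str, float] = field(default_factory=lambda: dict(tables.EMBOSS_PKA))

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.pka_table.values()):
            raise ValueError("all pKa values must be positive")


@dataclass(frozen=True)
class ManualFeatureVector:
    """The 35 engineered features of one peptide."""

    paac: np.ndarray  # 20 + lambda components
    length: int
    shannon: float
    gravy: float
    mol_weight: float
    charge: float

    def to_array(self) -> np.ndarray:
        return np.concatenate(
            [
                self.paac,
                [self.length, self.shannon, self.gravy, self.mol_weight, self.charge],
            ]
        )


@dataclass(frozen=True)
class EncodedSequence:
    """Integer index encoding (A=1 ... Y=20, 0 = padding) of fixed length."""

    indices: np.ndarray
    true_length: int


def aa_frequencies(seq: str) -> np.ndarray:
    """Relative frequency of each amino acid, in alphabet order; sums to 1."""
    if not seq:
        raise ValueError("empty sequence")
    counts = np.zeros(20)
    for ch in seq:
        counts[AA_TO_INDEX[ch] - 1] += 1
    return counts / counts.sum()


def coupling(ri: str, rj: str, scale_matrix: np.ndarray) -> float:
    """Squared property difference between two residues, averaged over the
    property scales: J(ri, rj) = (1/Gamma) sum_q [Phi_q(rj) - Phi_q(ri)]^2.

    Symmetric and non-negative. ``scale_matrix`` is Gamma x 20 as returned
    by :meth:`PAACParams.scale_matrix`.
    """
    i, j = AA_TO_INDEX[ri] - 1, AA_TO_INDEX[rj] - 1
    diff = scale_matrix[:, j] - scale_matrix[:, i]
    return float(np.mean(diff**2))


def tier_correlation(seq: str, k: int, scale_matrix: np.ndarray) -> float:
    """k-th tier correlation factor: mean coupling of residues k apart."""
    L = len(seq)
    if not 1 <= k < L:
        raise ValueError(f"tier k={k} requires 1 <= k < L={L}")
    idx = np.array([AA_TO_INDEX[ch] - 1 for ch in seq])
    props = scale_matrix[:, idx]  # Gamma x L
    diffs = props[:, k:] - props[:, :-k]
    return float((diffs**2).mean(axis=0).mean())


def paac(seq: str, params: PAACParams | None = None) -> np.ndarray:
    """Pseudo amino acid composition: 20 + lambda non-negative components
    summing to 1. Requires sequence length L > lambda."""
    params = params or PAACParams()
    L = len(seq)
    if L <= params.lam:
        raise ValueError(
            f"PAAC with lambda={params.lam} requires sequence length > lambda "
            f"(got L={L}); shorten lambda or drop the sequence"
        )
    freqs = aa_frequencies(seq)
    scales = params.scale_matrix()
    taus = np.array(
        [tier_correlation(seq, k, scales) for k in range(1, params.lam + 1)]
    )
    denom = freqs.sum() + params.w * taus.sum()
    return np.concatenate([freqs, params.w * taus]) / denom


def shannon_entropy(seq: str) -> float:
    """Shannon entropy of the amino-acid distribution, in nats; 0 for a
    homopolymer, ln 20 for a uniform full-alphabet composition."""
    freqs = aa_frequencies(seq)
    nz = freqs[freqs > 0]
    return float(-(nz * np.log(nz)).sum())


def gravy(seq: str, scale: dict[str, float] | None = None) -> float:
    """Grand average of hydropathy: mean Kyte-Doolittle value per residue."""
    if not seq:
        raise ValueError("empty sequence")
    scale = scale or tables.KYTE_DOOLITTLE
    return float(np.mean([scale[ch] for ch in seq]))


def molecular_weight(seq: str) -> float:
    """Average molecular weight in Daltons: sum of average residue masses
    plus one water for the termini."""
    if not seq:
        raise ValueError("empty sequence")
    return sum(tables.AVERAGE_RESIDUE_MASS[ch] for ch in seq) + tables.WATER_MASS


def charge_at_ph(seq: str, params: ChargeParams | None = None) -> float:
    """Net charge at the configured pH by Henderson-Hasselbalch fractions.

    Each basic group (N-terminus, K, R, H side chains) contributes
    +1/(1+10^(pH-pKa)); each acidic group (C-terminus, D, E, C, Y side
    chains) contributes -1/(1+10^(pKa-pH)).
    """
    if not seq:
        raise ValueError("empty sequence")
    params = params or ChargeParams()
    ph, pka = params.ph, params.pka_table

    def basic(pk: float) -> float:
        return 1.0 / (1.0 + 10.0 ** (ph - pk))

    def acidic(pk: float) -> float:
        return -1.0 / (1.0 + 10.0 ** (pk - ph))

    charge = basic(pka["Nterm"]) + acidic(pka["Cterm"])
    for ch in seq:
        if ch in tables.BASIC_RESIDUES:
            charge += basic(pka[ch])
        elif ch in tables.ACIDIC_RESIDUES:
            charge += acidic(pka[ch])
    return charge


def manual_features(
    seq: str,
    paac_params: PAACParams | None = None,
    charge_params: ChargeParams | None = None,
) -> ManualFeatureVector:
    """All 35 engineered features of one validated peptide."""
    return ManualFeatureVector(
        paac=paac(seq, paac_params),
        length=len(seq),
        shannon=shannon_entropy(seq),
        gravy=gravy(seq),
        mol_weight=molecular_weight(seq),
        charge=charge_at_ph(seq, charge_params),
    )


def index_encode(seq: str, max_len: int) -> EncodedSequence:
    """Map residues to integers (A=1 ... Y=20) and post-pad with 0 to
    ``max_len``; sequences longer than ``max_len`` are truncated with a
    logged warning."""
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    if len(seq) > max_len:
        logger.warning(
            "sequence of length %d truncated to max_len=%d", len(seq), max_len
        )
        seq = seq[:max_len]
    indices = np.zeros(max_len, dtype=np.int64)
    for i, ch in enumerate(seq):
        indices[i] = AA_TO_INDEX[ch]
    return EncodedSequence(indices=indices, true_length=len(seq))


def decode_indices(encoded: EncodedSequence) -> str:
    """Inverse of :func:`index_encode` for sequences that were not truncated."""
    return "".join(
        INDEX_TO_AA[int(i)] for i in encoded.indices[: encoded.true_length]
    )


def featurize_dataset(
    dataset: LabeledDataset,
    paac_params: PAACParams | None = None,
    charge_params: ChargeParams | None = None,
    max_len: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Featurize every peptide of a labeled dataset.

    Returns ``(manual, encoded, labels)`` with rows in dataset order:
    an N x 35 manual-feature matrix (columns per :data:`FEATURE_NAMES`),
    an N x max_len integer matrix for the embedding branch (``max_len``
    defaults to the longest sequence present), and the N labels.
    Fails fast, naming the offending peptide, if any sequence is invalid
    or shorter than lambda + 1.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    if max_len is None:
        max_len = max(len(p) for p in dataset)
    manual_rows, encoded_rows, labels = [], [], []
    for p in dataset:
        try:
            validate_sequence(p.seq, context=p.id)
            manual_rows.append(manual_features(p.seq, paac_params, charge_params).to_array())
            encoded_rows.append(index_encode(p.seq, max_len).indices)
        except ValueError as exc:
            raise ValueError(f"failed to featurize peptide {p.id!r}: {exc}") from exc
        labels.append(p.label)
    return (
        np.array(manual_rows),
        np.array(encoded_rows),
        np.array(labels, dtype=np.int64),
    )
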