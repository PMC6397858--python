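"""Mutual-information n-gram features for pre-miRNA sequences and structures.

The representation treats every window of 2 or 3 consecutive symbols as an
*unordered* n-gram (a multiset): "GA" and "AG" fall in the same bin. Over the
4-letter sequence alphabet this yields 10 distinct 2-grams and 20 distinct
3-grams; over the 3-symbol dot-bracket alphabet, 6 and 10.

From the window counts of a single sequence, smoothed frequencies

    p(x)     = (N_x   + eps) / L
    p(x,y)   = (N_xy  + eps) / (L - 1)
    p(x,y,z) = (N_xyz + eps) / (L - 2)

are formed (eps a tiny positive constant so every probability is strictly
positive), and three information quantities are computed per n-gram bin:

    MI(x,y)    = p(x,y) * log( p(x,y) / (p(x) p(y)) )          (pointwise)
    MI(x,y|z)  = H(x|z) - H(x|y,z)
                 with H(x|z)   = -(p(x,z)/p(z))    log( p(x,z)/p(z) )
                      H(x|y,z) = -(p(x,y,z)/p(y,z)) log( p(x,y,z)/p(y,z) )
    MI(x,y,z)  = MI(x,y) - MI(x,y|z)

MI(x,y,z) is not symmetric in its three roles, so roles are fixed by the
canonical ascending order of the multiset: x <= y <= z, with z the largest
symbol. All joint-probability lookups use unordered multisets, which makes
MI(x,y) = MI(y,x) hold by construction.

Terms follow the standard 0 log 0 = 0 convention: any MI or entropy term
whose joint n-gram was never observed contributes exactly zero. eps is a
numerical guard for the observed terms, not additive smoothing — because
the three probability estimates share no common denominator, carrying eps
through unobserved bins would leave an O(1/L^2) residue in the score, and
the smoothing constant is meant to have no effect on it. A homopolymer
therefore scores exactly zero for every unobserved n-gram bin.

The assembled vectors are:

* PSFMI (34): 20 triple-MI values over the lexicographic sequence 3-multisets,
  10 pair-MI values over the 2-multisets, and the 4 base frequencies N_x/L in
  order A, C, G, U.
* SSFMI (20): the analogous 10 + 6 MI values over the dot-bracket alphabet
  ("(" < "." < ")"), the 3 symbol frequencies, and the base-pair count (the
  number of "(" symbols; G-U wobble pairs are already pairs in the folded
  structure, so they are included).
* MFE (1): the structure's minimum free energy in kcal/mol.

PSFMI + SSFMI + MFE = 55 features in a fixed, named order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import folding
from .seqio import LabeledRecord, RnaSequence, SecondaryStructure

SEQUENCE_ALPHABET = "ACGU"
STRUCTURE_ALPHABET = "(.)"  # canonical order: "(" < "." < ")"

DEFAULT_EPSILON = 1e-8
DEFAULT_LOG_BASE = 2.0

#: readable aliases for structure symbols in feature names
_STRUCT_SYMBOL_NAME = {"(": "L", ".": "D", ")": "R"}


def multisets(alphabet: str, n: int) -> list[str]:
    """All unordered n-grams over ``alphabet`` in lexicographic (canonical
    alphabet) order, as sorted strings."""
    return ["".join(c) for c in combinations_with_replacement(alphabet, n)]


def multiset_key(symbols: Iterable[str], alphabet: str) -> str:
    """Canonical key of a symbol multiset: sorted by alphabet order."""
    return "".join(sorted(symbols, key=alphabet.index))


@dataclass(frozen=True)
class NgramCounts:
    """Unigram/2-gram/3-gram window counts of one string.

    Every possible multiset bin is present (zero-count bins included), so
    unigram counts sum to L, pair counts to L - 1, triple counts to L - 2.
    """

    L: int
    alphabet: str
    unigram: Mapping[str, int]
    pair: Mapping[str, int]
    triple: Mapping[str, int]


def count_ngrams(s: str, alphabet: str) -> NgramCounts:
    """Tally unordered 1/2/3-gram windows of ``s`` over ``alphabet``."""
    if len(s) < 4:
        raise ValueError(f"need length >= 4, got {len(s)}")
    uni = {k: 0 for k in alphabet}
    pair = {k: 0 for k in multisets(alphabet, 2)}
    triple = {k: 0 for k in multisets(alphabet, 3)}
    for ch in s:
        if ch not in alphabet:
            raise ValueError(f"symbol {ch!r} not in alphabet {alphabet!r}")
        uni[ch] += 1
    for i in range(len(s) - 1):
        pair[multiset_key(s[i : i + 2], alphabet)] += 1
    for i in range(len(s) - 2):
        triple[multiset_key(s[i : i + 3], alphabet)] += 1
    return NgramCounts(L=len(s), alphabet=alphabet, unigram=uni, pair=pair, triple=triple)


@dataclass(frozen=True)
class MiProbabilityModel:
    """Smoothed n-gram probabilities of one string, ready for MI evaluation.

    ``counts`` is retained so the MI functions can zero out terms whose
    joint n-gram was never observed (0 log 0 = 0 convention).
    """

    L: int
    alphabet: str
    epsilon: float
    log_base: float
    p1: Mapping[str, float]
    p2: Mapping[str, float]
    p3: Mapping[str, float]
    counts: NgramCounts

    def log(self, x: float) -> float:
        return math.log(x) / math.log(self.log_base)


def estimate_probs(
    counts: NgramCounts,
    epsilon: float = DEFAULT_EPSILON,
    log_base: float = DEFAULT_LOG_BASE,
) -> MiProbabilityModel:
    """Smoothed probabilities: epsilon is added to every bin's count,
    observed or not, so every probability is strictly positive."""
    if epsilon <= 0:
        raise ValueError(f"epsilon must be positive, got {epsilon}")
    L = counts.L
    return MiProbabilityModel(
        L=L,
        alphabet=counts.alphabet,
        epsilon=epsilon,
        log_base=log_base,
        p1={k: (v + epsilon) / L for k, v in counts.unigram.items()},
        p2={k: (v + epsilon) / (L - 1) for k, v in counts.pair.items()},
        p3={k: (v + epsilon) / (L - 2) for k, v in counts.triple.items()},
        counts=counts,
    )


def model_for(
    s: str,
    alphabet: str,
    epsilon: float = DEFAULT_EPSILON,
    log_base: float = DEFAULT_LOG_BASE,
) -> MiProbabilityModel:
    return estimate_probs(count_ngrams(s, alphabet), epsilon, log_base)


def pair_mi(model: MiProbabilityModel, x: str, y: str) -> float:
    """Pointwise mutual information of the unordered pair {x, y}.

    Zero when the pair was never observed as a window (0 log 0 = 0).
    """
    key = multiset_key((x, y), model.alphabet)
    if model.counts.pair[key] == 0:
        return 0.0
    pxy = model.p2[key]
    return pxy * model.log(pxy / (model.p1[x] * model.p1[y]))


def conditional_mi(model: MiProbabilityModel, x: str, y: str, z: str) -> float:
    """MI(x,y|z) = H(x|z) - H(x|y,z), all joint terms looked up as multisets.

    Each conditional-entropy term vanishes when its joint n-gram was never
    observed (its conditioning event then carries no information about x).
    """
    a = model.alphabet
    key_xz = multiset_key((x, z), a)
    key_xyz = multiset_key((x, y, z), a)
    if model.counts.pair[key_xz] == 0:
        h_x_given_z = 0.0
    else:
        r = model.p2[key_xz] / model.p1[z]
        h_x_given_z = -r * model.log(r)
    if model.counts.triple[key_xyz] == 0:
        h_x_given_yz = 0.0
    else:
        r = model.p3[key_xyz] / model.p2[multiset_key((y, z), a)]
        h_x_given_yz = -r * model.log(r)
    return h_x_given_z - h_x_given_yz


def triple_mi(model: MiProbabilityModel, triple: str) -> float:
    """3-tuple MI(x,y,z) = MI(x,y) - MI(x,y|z) with roles assigned by the
    canonical ascending order of the multiset (z = largest symbol)."""
    x, y, z = sorted(triple, key=model.alphabet.index)
    return pair_mi(model, x, y) - conditional_mi(model, x, y, z)


# ---------------------------------------------------------------------------
# feature-vector assembly


def _symbol_name(sym: str) -> str:
    return _STRUCT_SYMBOL_NAME.get(sym, sym)


def _block_names() -> tuple[list[str], list[str]]:
    ps = (
        [f"PSFMI_T_{t}" for t in multisets(SEQUENCE_ALPHABET, 3)]
        + [f"PSFMI_P_{p}" for p in multisets(SEQUENCE_ALPHABET, 2)]
        + [f"PSFMI_F_{c}" for c in SEQUENCE_ALPHABET]
    )
    ss = (
        [
            "SSFMI_T_" + "".join(_symbol_name(c) for c in t)
            for t in multisets(STRUCTURE_ALPHABET, 3)
        ]
        + [
            "SSFMI_P_" + "".join(_symbol_name(c) for c in p)
            for p in multisets(STRUCTURE_ALPHABET, 2)
        ]
        + [f"SSFMI_F_{_symbol_name(c)}" for c in STRUCTURE_ALPHABET]
        + ["SSFMI_BP"]
    )
    return ps, ss


PSFMI_NAMES, SSFMI_NAMES = _block_names()
FEATURE_NAMES: list[str] = PSFMI_NAMES + SSFMI_NAMES + ["MFE"]
N_FEATURES = len(FEATURE_NAMES)  # 34 + 20 + 1 = 55

#: column slices of the three feature blocks in the canonical layout
FEATURE_BLOCKS: dict[str, slice] = {
    "PSFMI": slice(0, 34),
    "SSFMI": slice(34, 54),
    "MFE": slice(54, 55),
}


def psfmi_features(
    seq: RnaSequence | str,
    epsilon: float = DEFAULT_EPSILON,
    log_base: float = DEFAULT_LOG_BASE,
) -> np.ndarray:
    """The 34 primary-sequence features: 20 triple-MI, 10 pair-MI, 4 base
    frequencies (raw N_x / L) in order A, C, G, U."""
    s = seq.residues if isinstance(seq, RnaSequence) else seq
    counts = count_ngrams(s, SEQUENCE_ALPHABET)
    model = estimate_probs(counts, epsilon, log_base)
    vals = [triple_mi(model, t) for t in multisets(SEQUENCE_ALPHABET, 3)]
    vals += [pair_mi(model, p[0], p[1]) for p in multisets(SEQUENCE_ALPHABET, 2)]
    vals += [counts.unigram[c] / counts.L for c in SEQUENCE_ALPHABET]
    return np.asarray(vals, dtype=float)


def ssfmi_features(
    struct: SecondaryStructure | str,
    epsilon: float = DEFAULT_EPSILON,
    log_base: float = DEFAULT_LOG_BASE,
) -> np.ndarray:
    """The 20 secondary-structure features: 10 triple-MI, 6 pair-MI, 3 symbol
    frequencies in order '(', '.', ')', and the base-pair count."""
    db = struct.dotbracket if isinstance(struct, SecondaryStructure) else struct
    counts = count_ngrams(db, STRUCTURE_ALPHABET)
    model = estimate_probs(counts, epsilon, log_base)
    vals = [triple_mi(model, t) for t in multisets(STRUCTURE_ALPHABET, 3)]
    vals += [pair_mi(model, p[0], p[1]) for p in multisets(STRUCTURE_ALPHABET, 2)]
    vals += [counts.unigram[c] / counts.L for c in STRUCTURE_ALPHABET]
    vals.append(float(db.count("(")))
    return np.asarray(vals, dtype=float)


@dataclass(frozen=True)
class FeatureVector:
    """One record's named 55-value feature vector."""

    id: str
    values: np.ndarray
    names: Sequence[str] = field(default=tuple(FEATURE_NAMES))

    def __post_init__(self) -> None:
        if len(self.values) != len(self.names):
            raise ValueError(
                f"{len(self.values)} values for {len(self.names)} names"
            )

    @property
    def psfmi(self) -> np.ndarray:
        return self.values[FEATURE_BLOCKS["PSFMI"]]

    @property
    def ssfmi(self) -> np.ndarray:
        return self.values[FEATURE_BLOCKS["SSFMI"]]

    @property
    def mfe(self) -> float:
        return float(self.values[54])


def extract_features(
    record: LabeledRecord | RnaSequence,
    epsilon: float = DEFAULT_EPSILON,
    log_base: float = DEFAULT_LOG_BASE,
    fold_backend: str = "nussinov",
    min_loop: int = folding.DEFAULT_MIN_LOOP,
) -> FeatureVector:
    """Full 55-feature vector of one record; folds on demand if the record
    carries no precomputed structure."""
    if isinstance(record, RnaSequence):
        record = LabeledRecord(sequence=record)
    struct = record.structure
    if struct is None:
        struct = folding.fold(record.sequence, backend=fold_backend, min_loop=min_loop)
    values = np.concatenate(
        [
            psfmi_features(record.sequence, epsilon, log_base),
            ssfmi_features(struct, epsilon, log_base),
            [struct.mfe],
        ]
    )
    return FeatureVector(id=record.sequence.id, values=values)


class MutualInformationFeaturizer(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer mapping sequence/structure records to the
    canonical 55-column feature matrix.

    Parameters
    ----------
    epsilon : float, default 1e-8
        Smoothing constant added to every n-gram count. Its only job is to
        keep all probabilities strictly positive; at the default it perturbs
        features by far less than any downstream tolerance.
    log_base : float, default 2
        Base of the logarithm in the MI formulas (2 = bits). Downstream
        min-max normalisation makes the choice immaterial to classification.
    fold_backend : str, default "nussinov"
        Backend used for records without a precomputed structure.
    min_loop : int, default 3
        Minimum hairpin loop size passed to the folding backend.

    The transformer is stateless: ``fit`` only validates the input and
    records ``n_features_out_``.
    """

    def __init__(
        self,
        epsilon: float = DEFAULT_EPSILON,
        log_base: float = DEFAULT_LOG_BASE,
        fold_backend: str = "nussinov",
        min_loop: int = folding.DEFAULT_MIN_LOOP,
    ):
        self.epsilon = epsilon
        self.log_base = log_base
        self.fold_backend = fold_backend
        self.min_loop = min_loop

    def fit(self, X: Sequence, y=None) -> "MutualInformationFeaturizer":
        self.n_features_out_ = N_FEATURES
        self.feature_names_out_ = list(FEATURE_NAMES)
        return self

    def transform(self, X: Sequence) -> np.ndarray:
        rows = [
            extract_features(
                self._coerce(rec),
                epsilon=self.epsilon,
                log_base=self.log_base,
                fold_backend=self.fold_backend,
                min_loop=self.min_loop,
            ).values
            for rec in X
        ]
        return np.vstack(rows) if rows else np.empty((0, N_FEATURES))

    def get_feature_names_out(self, input_features=None):
        return np.asarray(FEATURE_NAMES, dtype=object)

    @staticmethod
    def _coerce(rec) -> LabeledRecord:
        if isinstance(rec, LabeledRecord):
            return rec
        if isinstance(rec, RnaSequence):
            return LabeledRecord(sequence=rec)
        if isinstance(rec, tuple) and len(rec) == 2:
            return LabeledRecord(sequence=rec[0], structure=rec[1])
        if isinstance(rec, str):
            return LabeledRecord(sequence=RnaSequence.from_raw("<anonymous>", rec))
        raise TypeError(f"cannot interpret record of type {type(rec).__name__}")
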