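"""Sequence-derived protein descriptors and the 479-column feature schema.

Implements, natively from the amino-acid sequence:

* amino-acid composition (AAC, 20),
* Chou-style pseudo composition in four variants — amphiphilic (APAAC, 30),
  type-I with lambda=10 (PAAC, 30), type-I "parallel" with lambda=2
  (PsePC, 22) and type-II "serial" with lambda=2 over 3 properties
  (PseSC, 26),
* composition/transition/distribution descriptors over 7 physicochemical
  groupings (CTDC 21, CTDT 21, CTDD 105),
* Geary autocorrelation over 4 scalar properties at lags 1..10 (40),
* quasi-sequence-order descriptors and sequence-order coupling numbers
  under two residue distance matrices (QSO 60, SOCN 20),
* mean projections onto nine multi-dimensional property scales
  (Blosum 8 + 54 of the scalar/scale block),
* scalar physicochemical indices (net charge, Boman-type interaction index,
  aliphatic index, auto/cross-covariance, hydrophobic moments, mean
  hydrophobicity, instability index, isoelectric point).

Together with the 18 external-tool scores and the single GO-homology code
these form a fixed, ordered 479-name schema (:data:`FEATURE_SCHEMA`); block
sizes are exposed in :data:`BLOCKS`.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.SeqUtils.ProtParam import ProteinAnalysis
from sklearn.base import BaseEstimator, TransformerMixin

from . import scales
from .scales import (
    AA_INDEX,
    CHOU_TRIPLET,
    CTD_GROUPS,
    DISTANCE_MATRICES,
    GEARY_PROPERTIES,
    PKA,
    BLOSUM_SCALE,
    MULTI_SCALES,
    PropertyScale,
    residue_charge,
    standardized,
)
from .seqio import AA_ALPHABET, MIN_EXTRACTION_LENGTH, Dataset, ProteinRecord


class DescriptorError(ValueError):
    """Raised when a descriptor's preconditions are violated."""


@dataclass(frozen=True)
class DescriptorParams:
    """Tunable descriptor parameters.

    Lambda values are pinned per pseudo-composition block by the schema's
    printed dimensions (PsePC: 20+2=22, PseSC: 20+2*3=26, PAAC: 20+10=30,
    APAAC: 20+2*5=30); weights follow the 0.05 / 0.1 convention of the
    pseudo-composition literature.
    """

    lambda_parallel: int = 2
    lambda_serial: int = 2
    lambda_paac: int = 10
    lambda_apaac: int = 5
    weight_parallel: float = 0.05
    weight_serial: float = 0.05
    weight_paac: float = 0.1
    weight_apaac: float = 0.1
    nlag: int = 10
    qso_weight: float = 0.1

    def __post_init__(self):
        for name in ("lambda_parallel", "lambda_serial", "lambda_paac", "lambda_apaac"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("weight_parallel", "weight_serial", "weight_paac", "weight_apaac"):
            w = getattr(self, name)
            if not 0 < w <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.nlag < 1:
            raise ValueError("nlag must be >= 1")


DEFAULT_PARAMS = DescriptorParams()


def _indices(sequence: str) -> np.ndarray:
    try:
        return np.array([AA_INDEX[aa] for aa in sequence], dtype=np.intp)
    except KeyError as exc:
        raise DescriptorError(f"invalid residue {exc.args[0]!r}") from exc


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------


def aac(sequence: str) -> np.ndarray:
    """Amino-acid composition: frequency of each residue, alphabetical order."""
    if not sequence:
        raise DescriptorError("empty sequence")
    idx = _indices(sequence)
    return np.bincount(idx, minlength=20) / len(sequence)


# ---------------------------------------------------------------------------
# Pseudo amino-acid composition (four variants)
# ---------------------------------------------------------------------------


def pseaac(
    sequence: str,
    mode: str,
    lam: int | None = None,
    weight: float | None = None,
    params: DescriptorParams = DEFAULT_PARAMS,
) -> np.ndarray:
    """Pseudo composition vector in one of four modes.

    ``parallel`` / ``paac``: Chou type I — lambda correlation factors, each the
    mean squared property difference over the hydrophobicity / hydrophilicity /
    side-chain-mass triplet; dimension 20 + lambda.
    ``serial``: Chou type II — one factor per property and lag (lag-major
    order); dimension 20 + lambda * 3.
    ``apaac``: amphiphilic — per lag, one hydrophobicity and one
    hydrophilicity product-correlation factor; dimension 20 + 2 * lambda.

    The first 20 components reduce to the (weight-damped) composition.
    """
    defaults = {
        "parallel": (params.lambda_parallel, params.weight_parallel),
        "serial": (params.lambda_serial, params.weight_serial),
        "paac": (params.lambda_paac, params.weight_paac),
        "apaac": (params.lambda_apaac, params.weight_apaac),
    }
    if mode not in defaults:
        raise DescriptorError(f"unknown pseaac mode {mode!r}")
    d_lam, d_w = defaults[mode]
    lam = d_lam if lam is None else lam
    weight = d_w if weight is None else weight
    L = len(sequence)
    if L <= lam:
        raise DescriptorError(
            f"pseaac mode={mode}: sequence length {L} must exceed lambda={lam}"
        )
    idx = _indices(sequence)
    props = CHOU_TRIPLET[:, idx]  # (3, L) standardized property values
    freqs = aac(sequence)

    if mode in ("parallel", "paac"):
        theta = np.empty(lam)
        for k in range(1, lam + 1):
            diff = props[:, k:] - props[:, :-k]  # (3, L-k)
            theta[k - 1] = np.mean(diff**2)
    elif mode == "serial":
        theta = np.empty(lam * 3)
        pos = 0
        for k in range(1, lam + 1):  # lag-major, property-minor
            diff = props[:, k:] - props[:, :-k]
            theta[pos : pos + 3] = np.mean(diff**2, axis=1)
            pos += 3
    else:  # apaac
        theta = np.empty(2 * lam)
        for k in range(1, lam + 1):
            for j in (0, 1):  # hydrophobicity, hydrophilicity
                theta[2 * (k - 1) + j] = np.mean(props[j, :-k] * props[j, k:])

    denom = 1.0 + weight * theta.sum()
    if denom <= 1e-9:
        raise DescriptorError(
            f"pseaac mode={mode}: degenerate normalization denominator {denom:g}"
        )
    return np.concatenate([freqs, weight * theta]) / denom


# ---------------------------------------------------------------------------
# CTD
# ---------------------------------------------------------------------------

_CTD_CODES = {
    prop: {aa: g for g, members in enumerate(groups) for aa in members}
    for prop, groups in CTD_GROUPS.items()
}
_CTD_QUANTILES = (0.0, 0.25, 0.50, 0.75, 1.0)


def ctd(sequence: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Composition (21), transition (21) and distribution (105) descriptors.

    Per property: C = the three group frequencies; T = counts of unordered
    adjacent group transitions (pairs 1-2, 1-3, 2-3) normalized by the number
    of group-changing adjacent pairs (zeros when none); D = for each group the
    sequence position, as percent of length, of its first, 25%, 50%, 75% and
    last occurrence (ceil rule; zeros for an absent group).
    """
    L = len(sequence)
    if L < 1:
        raise DescriptorError("empty sequence")
    C, T, D = [], [], []
    for prop in CTD_GROUPS:
        codes = np.array([_CTD_CODES[prop][aa] for aa in sequence])
        counts = np.bincount(codes, minlength=3)
        C.extend(counts / L)
        if L >= 2:
            a, b = codes[:-1], codes[1:]
            hetero = a != b
            n_hetero = int(hetero.sum())
            pair_counts = []
            for g1, g2 in ((0, 1), (0, 2), (1, 2)):
                n = int(np.sum(((a == g1) & (b == g2)) | ((a == g2) & (b == g1))))
                pair_counts.append(n)
            if n_hetero:
                T.extend(c / n_hetero for c in pair_counts)
            else:
                T.extend([0.0, 0.0, 0.0])
        else:
            T.extend([0.0, 0.0, 0.0])
        for g in range(3):
            positions = np.flatnonzero(codes == g) + 1  # 1-based
            n = len(positions)
            if n == 0:
                D.extend([0.0] * 5)
                continue
            for q in _CTD_QUANTILES:
                k = max(1, math.ceil(q * n))
                D.append(100.0 * positions[k - 1] / L)
    return np.array(C), np.array(T), np.array(D)


# ---------------------------------------------------------------------------
# Geary autocorrelation
# ---------------------------------------------------------------------------


def geary(
    sequence: str,
    properties: dict | None = None,
    nlag: int = 10,
) -> np.ndarray:
    """Geary coefficient c(k), k=1..nlag, per scalar property (4 x 10 = 40).

    c(k) = [(L-1) * sum_i (x_i - x_{i+k})^2] / [2 (L-k) * sum_i (x_i - xbar)^2]
    on standardized property values; a zero-variance (e.g. homopolymer) input
    yields c(k) = 1, the no-autocorrelation fixpoint.
    """
    properties = GEARY_PROPERTIES if properties is None else properties
    L = len(sequence)
    if L <= nlag:
        raise DescriptorError(f"geary: sequence length {L} must exceed nlag={nlag}")
    idx = _indices(sequence)
    out = []
    for table in properties.values():
        x = standardized(table)[idx]
        denom = np.sum((x - x.mean()) ** 2)
        if denom < 1e-12 * L:  # zero-variance input (rounding-safe)
            denom = 0.0
        for k in range(1, nlag + 1):
            if denom == 0:
                out.append(1.0)
                continue
            num = (L - 1) * np.sum((x[:-k] - x[k:]) ** 2)
            out.append(num / (2.0 * (L - k) * denom))
    return np.array(out)


# ---------------------------------------------------------------------------
# Quasi-sequence-order
# ---------------------------------------------------------------------------


def qso_socn(
    sequence: str, nlag: int = 10, weight: float = 0.1
) -> tuple[np.ndarray, np.ndarray]:
    """Quasi-sequence-order (60) and sequence-order coupling numbers (20).

    For each of the two residue distance matrices: tau_d = sum over sequence
    of the squared distance between residues d apart, d = 1..nlag (SOCN);
    QSO = the 20 residue counts and the nlag weighted coupling numbers,
    jointly normalized by (sum f + w * sum tau).
    """
    L = len(sequence)
    if L <= nlag:
        raise DescriptorError(f"qso: sequence length {L} must exceed nlag={nlag}")
    idx = _indices(sequence)
    counts = np.bincount(idx, minlength=20).astype(float)
    qso_parts, socn_parts = [], []
    for D in DISTANCE_MATRICES.values():
        tau = np.empty(nlag)
        for d in range(1, nlag + 1):
            tau[d - 1] = np.sum(D[idx[:-d], idx[d:]] ** 2)
        socn_parts.append(tau)
        denom = counts.sum() + weight * tau.sum()
        qso_parts.append(np.concatenate([counts, weight * tau]) / denom)
    return np.concatenate(qso_parts), np.concatenate(socn_parts)


# ---------------------------------------------------------------------------
# Scale projections and scalar physicochemical indices
# ---------------------------------------------------------------------------


def scale_projection(sequence: str, scale: PropertyScale) -> np.ndarray:
    """Arithmetic mean over residues of each of the scale's d components."""
    if not sequence:
        raise DescriptorError("empty sequence")
    idx = _indices(sequence)
    return scale.matrix()[idx].mean(axis=0)


def isoelectric_point(sequence: str, tol: float = 1e-4) -> float:
    """pH at which the net charge is zero (bisection on [0, 14])."""
    counts = Counter(sequence)
    lo, hi = 0.0, 14.0
    # net charge is monotonically decreasing in pH
    if residue_charge(counts, lo) < 0:
        return lo
    if residue_charge(counts, hi) > 0:
        return hi
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if residue_charge(counts, mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def hydrophobic_moment(
    sequence: str, angle_deg: float, window: int = 11
) -> float:
    """Maximum per-window hydrophobic moment (Eisenberg scale).

    uH = |sum_j h_j * e^(i * j * delta)| / w over a sliding window (the full
    sequence when shorter); angle 100 deg probes alpha-helix periodicity,
    160 deg beta-sheet.
    """
    h = scales._vec(scales.EISENBERG)[_indices(sequence)]
    delta = math.radians(angle_deg)
    w = min(window, len(h))
    best = 0.0
    angles = delta * np.arange(w)
    sin_a, cos_a = np.sin(angles), np.cos(angles)
    for start in range(len(h) - w + 1):
        seg = h[start : start + w]
        m = math.hypot(float(seg @ sin_a), float(seg @ cos_a)) / w
        best = max(best, m)
    return best


def _covariance_index(x: np.ndarray, y: np.ndarray, nlag: int) -> float:
    """Mean over lags 1..nlag of the lagged cross products (auto when x is y)."""
    L = len(x)
    nlag = min(nlag, L - 1)
    vals = [float(np.mean(x[:-k] * y[k:])) for k in range(1, nlag + 1)]
    return float(np.mean(vals))


def physchem_indices(sequence: str, nlag: int = 10) -> dict[str, float]:
    """Scalar physicochemical indices (the non-scale part of the scalar block).

    Boman-type interaction index = mean residue transfer free energy (Guy
    scale); aliphatic index per Ikai; instability index per the published
    dipeptide-weight formula (via Biopython); pI by bisection on the
    EMBOSS-style pKa table.
    """
    L = len(sequence)
    if L < 1:
        raise DescriptorError("empty sequence")
    idx = _indices(sequence)
    f = aac(sequence)
    kd_std = standardized(scales.HYDROPHOBICITY_KD)[idx]
    hw_std = standardized(scales.HYDROPHILICITY_HW)[idx]
    out = {
        "Charge": residue_charge(Counter(sequence), 7.0),
        "Boman": float(scales._vec(scales.TRANSFER_GUY)[idx].mean()),
        "aIndex": 100.0 * f[AA_INDEX["A"]]
        + 2.9 * 100.0 * f[AA_INDEX["V"]]
        + 3.9 * (100.0 * f[AA_INDEX["I"]] + 100.0 * f[AA_INDEX["L"]]),
        "autocov": _covariance_index(kd_std, kd_std, nlag),
        "Crosscov1": _covariance_index(kd_std, hw_std, nlag),
        "Crosscov2": _covariance_index(hw_std, kd_std, nlag),
        "Hmoment1": hydrophobic_moment(sequence, 100.0),
        "Hmoment2": hydrophobic_moment(sequence, 160.0),
        "hydrophobicity": float(scales._vec(scales.HYDROPHOBICITY_KD)[idx].mean()),
        "pI": isoelectric_point(sequence),
    }
    if L < 2:
        raise DescriptorError("instability index undefined for length < 2")
    out["Instaindex"] = ProteinAnalysis(sequence).instability_index()
    return out


# ---------------------------------------------------------------------------
# Schema
# ---------------------------------------------------------------------------


def _range_names(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i}" for i in range(1, n + 1)]


#: External-tool score columns, in schema order.
EXTERNAL_FEATURE_NAMES: tuple[str, ...] = (
    "cTP",
    "mTP",
    "SP",
    "TM",
    "other",
    "NLS",
    "erpred",
    "SVM_mito",
    "SVM_mem",
    "SVM_inter",
    "SVM_matrix",
    "SVM_outer",
    "Tango1",
    "Tango2",
    "Tango3",
    "Tango4",
    "Tango5",
    "Tango6",
)

_SCALAR_BLOCK_NAMES = (
    ["Charge", "Boman", "aIndex", "autocov", "Crosscov1", "Crosscov2"]
    + _range_names("Crucian", 3)
    + _range_names("fasgai", 6)
    + ["Hmoment1", "Hmoment2", "hydrophobicity", "Instaindex"]
    + _range_names("mswhimscore", 3)
    + ["pI"]
    + _range_names("protFP", 8)
    + _range_names("stscales", 8)
    + _range_names("tscales", 5)
    + _range_names("vhsescales", 8)
    + _range_names("zscales", 5)
)

#: Block name -> ordered feature names (schema block order).
BLOCKS: dict[str, list[str]] = {
    "AAC": _range_names("AAC", 20),
    "APAAC": _range_names("APAAC", 30),
    "Blosum": _range_names("Blosum", 8),
    "CTDC": _range_names("CTDC", 21),
    "CTDD": _range_names("CTDD", 105),
    "CTDT": _range_names("CTDT", 21),
    "Geary": _range_names("Geary", 40),
    "PAAC": _range_names("PAAC", 30),
    "PsePC": _range_names("PsePC", 22),
    "PseSC": _range_names("PseSC", 26),
    "Scalar": _SCALAR_BLOCK_NAMES,
    "QSO": _range_names("QSO", 60),
    "SOCN": _range_names("SOCN", 20),
    "External": list(EXTERNAL_FEATURE_NAMES),
    "Homology": ["Homology"],
}

#: The full ordered 479-name feature schema.
FEATURE_SCHEMA: tuple[str, ...] = tuple(
    name for names in BLOCKS.values() for name in names
)
assert len(FEATURE_SCHEMA) == 479
assert len(set(FEATURE_SCHEMA)) == 479

_SCALE_ORDER = {  # schema scale-block prefix -> scale key
    "Crucian": "cruciani",
    "fasgai": "fasgai",
    "mswhimscore": "mswhim",
    "protFP": "protfp",
    "stscales": "stscales",
    "tscales": "tscales",
    "vhsescales": "vhse",
    "zscales": "zscales",
}


def schema_json() -> str:
    """The 479-name schema as JSON (for exact column-order pinning)."""
    return json.dumps(list(FEATURE_SCHEMA))


# ---------------------------------------------------------------------------
# Full extraction
# ---------------------------------------------------------------------------


def extract_features(
    record: ProteinRecord,
    external,
    params: DescriptorParams = DEFAULT_PARAMS,
) -> np.ndarray:
    """Encode one protein as the full ordered 479-value feature vector.

    ``external`` is an :class:`~plantloc.external_scores.ExternalScores` (real
    or mock); its 18 values and the homology code fill the last two blocks.
    Deterministic given inputs.
    """
    seq = record.sequence
    if len(seq) < MIN_EXTRACTION_LENGTH:
        raise DescriptorError(
            f"record {record.id!r}: length {len(seq)} < minimum "
            f"{MIN_EXTRACTION_LENGTH} for sequence-order descriptors"
        )
    parts: list[np.ndarray] = []
    try:
        block = "AAC"
        parts.append(aac(seq))
        block = "APAAC"
        parts.append(pseaac(seq, "apaac", params=params))
        block = "Blosum"
        parts.append(scale_projection(seq, BLOSUM_SCALE))
        block = "CTD"
        C, T, D = ctd(seq)
        parts.append(C)
        parts.append(D)
        parts.append(T)
        block = "Geary"
        parts.append(geary(seq, nlag=params.nlag))
        block = "PAAC"
        parts.append(pseaac(seq, "paac", params=params))
        block = "PsePC"
        parts.append(pseaac(seq, "parallel", params=params))
        block = "PseSC"
        parts.append(pseaac(seq, "serial", params=params))
        block = "Scalar"
        scalars = physchem_indices(seq, nlag=params.nlag)
        projections = {
            prefix: scale_projection(seq, MULTI_SCALES[key])
            for prefix, key in _SCALE_ORDER.items()
        }
        vals = []
        for name in _SCALAR_BLOCK_NAMES:
            if name in scalars:
                vals.append(scalars[name])
            else:
                prefix = name.rstrip("0123456789")
                comp = int(name[len(prefix) :]) - 1
                vals.append(projections[prefix][comp])
        parts.append(np.array(vals))
        block = "QSO/SOCN"
        qso, socn = qso_socn(seq, nlag=params.nlag, weight=params.qso_weight)
        parts.append(qso)
        parts.append(socn)
        block = "External"
        parts.append(external.to_array())
        block = "Homology"
        parts.append(np.array([float(getattr(external, "homology", 0))]))
    except DescriptorError as exc:
        raise DescriptorError(f"record {record.id!r}, block {block}: {exc}") from exc
    vec = np.concatenate(parts)
    if vec.shape != (479,):
        raise DescriptorError(
            f"record {record.id!r}: feature vector has length {len(vec)}, expected 479"
        )
    if not np.all(np.isfinite(vec)):
        bad = [FEATURE_SCHEMA[i] for i in np.flatnonzero(~np.isfinite(vec))]
        raise DescriptorError(f"record {record.id!r}: non-finite features {bad[:5]}")
    return vec


def extract_table(
    dataset: Dataset,
    provider,
    params: DescriptorParams = DEFAULT_PARAMS,
    on_error: str = "raise",
) -> pd.DataFrame:
    """Encode a dataset as an (n, 479) feature table indexed by record id.

    ``provider`` maps a record to its ExternalScores (a callable, or a dict
    keyed by id). ``on_error='skip'`` drops failing records (collecting their
    ids in ``df.attrs['failed']``) instead of raising.
    """
    rows, ids, failed = [], [], []
    for rec in dataset:
        ext = provider[rec.id] if hasattr(provider, "__getitem__") else provider(rec)
        try:
            rows.append(extract_features(rec, ext, params))
            ids.append(rec.id)
        except DescriptorError:
            if on_error != "skip":
                raise
            failed.append(rec.id)
    df = pd.DataFrame(
        np.vstack(rows) if rows else np.empty((0, 479)),
        index=pd.Index(ids, name="id"),
        columns=list(FEATURE_SCHEMA),
    )
    df.attrs["failed"] = failed
    return df


def write_feature_table(df: pd.DataFrame, path) -> None:
    """Write a feature table as TSV (12 significant digits, id first column)."""
    df.to_csv(path, sep="\t", float_format="%.12g", index=True)


def read_feature_table(path) -> pd.DataFrame:
    """Read a feature table TSV written by :func:`write_feature_table`."""
    df = pd.read_csv(path, sep="\t", index_col="id")
    return df


class FeatureExtractor(BaseEstimator, TransformerMixin):
    """Stateless transformer: protein records -> (n, 479) feature matrix.

    Parameters
    ----------
    provider : callable or mapping, optional
        Supplies ExternalScores per record; defaults to a deterministic mock
        (seeded by ``seed``) so the transformer runs with no external tools.
    params : DescriptorParams
    seed : int
        Seed for the default mock provider.
    """

    def __init__(self, provider=None, params: DescriptorParams = DEFAULT_PARAMS, seed: int = 0):
        self.provider = provider
        self.params = params
        self.seed = seed

    def fit(self, X, y=None):
        self.n_features_out_ = len(FEATURE_SCHEMA)
        return self

    def _resolve_provider(self):
        if self.provider is not None:
            return self.provider
        from .external_scores import MockScoreProvider

        return MockScoreProvider(seed=self.seed)

    def transform(self, X) -> pd.DataFrame:
        dataset = X if isinstance(X, Dataset) else Dataset(list(X))
        return extract_table(dataset, self._resolve_provider(), self.params)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(FEATURE_SCHEMA, dtype=object)
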