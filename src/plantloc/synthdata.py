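"""Labeled synthetic protein datasets with per-compartment structure.

The generator emulates just enough statistical structure for the full
pipeline to be exercised and validated with no downloads: each compartment
gets a composition signature (three amino acids boosted over a realistic
background, scaled by ``signal_strength``), a few compartments additionally
carry sorting-signal-like motifs (an N-terminal Arg/Ser-rich transit-peptide
stand-in for plastid, a basic K/R block for nucleus, a hydrophobic
transmembrane-like block for the cell membrane, an Arg/Leu-rich N-terminus
for mitochondrion), and mock external scores are biased toward the class at
the same strength. Dual-location records mix the two parent signatures
50/50. Everything is reproducible from the config seed.

Class counts default to the imbalance shape of curated plant datasets
(plastid-heavy, only a handful of cell-wall proteins) at reduced scale,
about 570 records in total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .external_scores import ExternalScores, MockScoreProvider
from .seqio import AA_ALPHABET, COMPARTMENTS, Dataset, ProteinRecord

#: Roughly UniProt-like background amino-acid frequencies.
BACKGROUND = {
    "A": 0.083, "R": 0.055, "N": 0.040, "D": 0.054, "C": 0.014, "Q": 0.039,
    "E": 0.067, "G": 0.071, "H": 0.022, "I": 0.059, "L": 0.096, "K": 0.058,
    "M": 0.024, "F": 0.039, "P": 0.047, "S": 0.066, "T": 0.053, "W": 0.011,
    "Y": 0.029, "V": 0.068,
}

#: Three boosted residues per compartment (the composition signature).
CLASS_SIGNATURES: dict[str, str] = {
    "plastid": "RSA",
    "cytoplasm": "DEG",
    "extracellular": "CGY",
    "nucleus": "KRP",
    "mitochondrion": "LRM",
    "cell_membrane": "FIL",
    "golgi": "PTN",
    "er": "HWV",
    "vacuole": "NQT",
    "peroxisome": "MQH",
    "cell_wall": "GPY",
}

#: Sorting-signal-like motif blocks (alphabet, length, N-terminal?).
CLASS_MOTIFS: dict[str, tuple[str, int, bool]] = {
    "plastid": ("RS", 20, True),
    "mitochondrion": ("RL", 15, True),
    "nucleus": ("KR", 8, False),
    "cell_membrane": ("ILVF", 19, False),
}

#: The three observed dual-location classes.
PAIR_CLASSES: tuple[tuple[str, str], ...] = (
    ("mitochondrion", "plastid"),
    ("cytoplasm", "nucleus"),
    ("cytoplasm", "golgi"),
)

#: Default per-class counts: plant-dataset imbalance shape at reduced scale.
DEFAULT_N_PER_CLASS = {
    "plastid": 100,
    "cytoplasm": 54,
    "extracellular": 22,
    "nucleus": 88,
    "mitochondrion": 69,
    "cell_membrane": 68,
    "golgi": 32,
    "er": 43,
    "vacuole": 27,
    "peroxisome": 9,
    "cell_wall": 8,
}
DEFAULT_N_PER_PAIR = {
    ("mitochondrion", "plastid"): 18,
    ("cytoplasm", "nucleus"): 26,
    ("cytoplasm", "golgi"): 5,
}

#: Composition boost added to each signature residue at full signal.
SIGNATURE_BOOST = 0.06


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic dataset."""

    n_per_class: dict = field(default_factory=lambda: dict(DEFAULT_N_PER_CLASS))
    n_per_pair: dict = field(default_factory=lambda: dict(DEFAULT_N_PER_PAIR))
    length_range: tuple[int, int] = (50, 400)
    signal_strength: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.signal_strength <= 1.0:
            raise ValueError("signal_strength must be in [0, 1]")
        if self.length_range[0] < 11 or self.length_range[0] > self.length_range[1]:
            raise ValueError("length_range must satisfy 11 <= lo <= hi")
        for cls, n in self.n_per_class.items():
            if cls not in COMPARTMENTS:
                raise ValueError(f"unknown compartment {cls!r}")
            if n < 2:
                raise ValueError(f"n_per_class[{cls!r}] must be >= 2")
        for pair in self.n_per_pair:
            if tuple(pair) not in PAIR_CLASSES:
                raise ValueError(f"unknown pair class {pair!r}")


def class_composition(labels, signal_strength: float) -> np.ndarray:
    """Signature-perturbed residue distribution for a (possibly dual) class."""
    base = np.array([BACKGROUND[aa] for aa in AA_ALPHABET])
    comps = []
    for lab in labels:
        comp = base.copy()
        for aa in CLASS_SIGNATURES[lab]:
            comp[AA_ALPHABET.index(aa)] += SIGNATURE_BOOST * signal_strength
        comps.append(comp / comp.sum())
    return np.mean(comps, axis=0)


def _draw_sequence(rng, labels, length: int, signal_strength: float) -> str:
    comp = class_composition(labels, signal_strength)
    seq = list(rng.choice(list(AA_ALPHABET), size=length, p=comp))
    if signal_strength > 0:
        for lab in labels:
            motif = CLASS_MOTIFS.get(lab)
            if motif is None or rng.random() >= signal_strength:
                continue
            alphabet, m_len, n_term = motif
            m_len = min(m_len, length)
            block = rng.choice(list(alphabet), size=m_len)
            start = 0 if n_term else int(rng.integers(0, length - m_len + 1))
            seq[start : start + m_len] = block
    return "".join(seq)


def generate(config: SyntheticConfig = SyntheticConfig()):
    """Generate (labeled Dataset, per-record ExternalScores dict).

    Sequences are i.i.d. draws from the class composition with optional motif
    blocks; mock external scores are biased by the class labels at strength
    ``signal_strength``. Identical configs produce identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    records = []
    groups = [((cls,), n) for cls, n in config.n_per_class.items()]
    groups += [(tuple(pair), n) for pair, n in config.n_per_pair.items()]
    for labels, n in groups:
        stem = "_".join(labels)
        for i in range(n):
            length = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
            seq = _draw_sequence(rng, labels, length, config.signal_strength)
            records.append(
                ProteinRecord(id=f"{stem}_{i:04d}", sequence=seq, labels=frozenset(labels))
            )
    dataset = Dataset(records)
    provider = MockScoreProvider(
        seed=config.seed + 1, strength=config.signal_strength, use_labels=True
    )
    scores: dict[str, ExternalScores] = {r.id: provider(r) for r in dataset}
    return dataset, scores


FIXTURES: dict[str, SyntheticConfig] = {
    # 22 records, 2 classes: fast smoke fixture
    "tiny": SyntheticConfig(
        n_per_class={"cytoplasm": 11, "nucleus": 11},
        n_per_pair={},
        length_range=(50, 120),
        seed=7,
    ),
    # balanced, zero signal: downstream accuracy should sit at chance (1/11)
    "null": SyntheticConfig(
        n_per_class={c: 20 for c in COMPARTMENTS},
        n_per_pair={},
        signal_strength=0.0,
        seed=11,
    ),
    # the study defaults: full imbalance shape, full signal
    "strong": SyntheticConfig(seed=13),
    # sharper imbalance (max/min class ratio 16), no pairs
    "imbalanced": SyntheticConfig(
        n_per_class={
            "plastid": 128, "cytoplasm": 48, "extracellular": 16, "nucleus": 96,
            "mitochondrion": 64, "cell_membrane": 64, "golgi": 24, "er": 32,
            "vacuole": 16, "peroxisome": 8, "cell_wall": 8,
        },
        n_per_pair={},
        seed=17,
    ),
}


def make_fixture(name: str):
    """Canned seeded datasets: tiny, null, strong, imbalanced."""
    if name not in FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; choose from {sorted(FIXTURES)}")
    return generate(FIXTURES[name])
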