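"""Sequence and label I/O for the localization pipeline.

Defines the canonical 11-compartment label universe, the validated protein
record/dataset containers, and readers for FASTA and the package's label TSV
dialect (``id<TAB>label1[<TAB>label2]``, ``#`` comments ignored).

Every downstream module receives only records validated here: upper-case
sequences over the 20 standard amino-acid letters, with at most two
compartment labels per protein (the multi-location classes observed in plant
proteomes are pairs such as mitochondrion+plastid or cytoplasm+nucleus).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Canonical compartment codes, in fixed classifier order.
COMPARTMENTS: tuple[str, ...] = (
    "plastid",
    "cytoplasm",
    "extracellular",
    "nucleus",
    "mitochondrion",
    "cell_membrane",
    "golgi",
    "er",
    "vacuole",
    "peroxisome",
    "cell_wall",
)

#: Accepted synonyms (case-insensitive) for compartment codes.
_SYNONYMS = {
    "chloroplast": "plastid",
    "cyto": "cytoplasm",
    "mito": "mitochondrion",
    "plasma_membrane": "cell_membrane",
    "membrane": "cell_membrane",
    "golgi_apparatus": "golgi",
    "endoplasmic_reticulum": "er",
    "extracellular_space": "extracellular",
}

#: The 20 standard amino-acid letters, alphabetical.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AA_ALPHABET)

#: Default mapping for ambiguous/non-standard residue letters.
AMBIGUITY_MAP = {"U": "C", "O": "K", "B": "N", "Z": "Q", "J": "L"}

#: Minimum sequence length accepted for feature extraction: sequence-order
#: descriptors with nlag=10 are undefined below nlag+1 residues.
MIN_EXTRACTION_LENGTH = 11


class SequenceError(ValueError):
    """Raised for malformed FASTA input or invalid residues."""


class LabelError(ValueError):
    """Raised for unknown compartment labels or malformed label files."""


def normalize_label(label: str) -> str:
    """Map a user-supplied compartment string to its canonical code.

    Raises :class:`LabelError` for strings outside the 11-code universe.
    """
    code = label.strip().lower().replace(" ", "_").replace("-", "_")
    code = _SYNONYMS.get(code, code)
    if code not in COMPARTMENTS:
        raise LabelError(
            f"unknown compartment {label!r}; valid codes: {', '.join(COMPARTMENTS)}"
        )
    return code


def clean_sequence(raw: str, policy: str = "map") -> str:
    """Normalize a raw amino-acid string to the 20-letter alphabet.

    policy='map' (default): upper-case, map U->C, O->K, B->N, Z->Q, J->L and
    drop X (descriptor formulas are defined only over the canonical letters).
    policy='drop-residue': drop every non-canonical letter.
    policy='reject': raise on any non-canonical letter.
    """
    if policy not in {"map", "drop-residue", "reject"}:
        raise ValueError(f"unknown ambiguity policy {policy!r}")
    seq = raw.strip().upper()
    out = []
    for ch in seq:
        if ch in _AA_SET:
            out.append(ch)
        elif policy == "reject":
            raise SequenceError(f"non-standard residue {ch!r} under policy='reject'")
        elif policy == "map":
            mapped = AMBIGUITY_MAP.get(ch)
            if mapped is not None:
                out.append(mapped)
            elif ch != "X" and not ch.isspace():
                if ch != "*":
                    raise SequenceError(f"invalid character {ch!r} in sequence")
        # drop-residue: silently skip
    return "".join(out)


@dataclass(frozen=True)
class ProteinRecord:
    """An identified amino-acid sequence with 0-2 compartment labels."""

    id: str
    sequence: str
    labels: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if not self.id:
            raise SequenceError("record id must be non-empty")
        if len(self.sequence) < 1:
            raise SequenceError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - _AA_SET
        if bad:
            raise SequenceError(
                f"record {self.id!r}: invalid residues {sorted(bad)}; "
                "run clean_sequence first"
            )
        if len(self.labels) > 2:
            raise LabelError(f"record {self.id!r}: more than 2 labels")
        for lab in self.labels:
            if lab not in COMPARTMENTS:
                raise LabelError(f"record {self.id!r}: unknown label {lab!r}")

    def with_labels(self, labels) -> "ProteinRecord":
        return replace(self, labels=frozenset(labels))


@dataclass
class Dataset:
    """Ordered collection of protein records with unique ids."""

    records: list[ProteinRecord]

    def __post_init__(self):
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise SequenceError(f"duplicate record ids: {dupes}")

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, key):
        if isinstance(key, str):
            return self._index()[key]
        return self.records[key]

    def _index(self) -> dict[str, ProteinRecord]:
        return {r.id: r for r in self.records}

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def labeled(self) -> "Dataset":
        """Subset of records carrying at least one label."""
        return Dataset([r for r in self.records if r.labels])


def read_fasta(path, policy: str = "map") -> Dataset:
    """Read a protein FASTA file into a validated :class:`Dataset`.

    One record per entry, in file order; sequences upper-cased and cleaned
    under the given ambiguity policy. Raises :class:`SequenceError` on
    malformed or empty input.
    """
    records = []
    def _first_bad_line():
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if line.strip():
                    if not line.startswith(">"):
                        return lineno
                    return None
        return None

    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except Exception as exc:
        bad = _first_bad_line()
        where = f"line {bad}" if bad else "file"
        raise SequenceError(
            f"{path}: {where} is not FASTA (expected '>' header)"
        ) from exc
    if not parsed:
        bad = _first_bad_line()
        if bad:
            raise SequenceError(f"{path}: line {bad} is not FASTA (expected '>' header)")
        raise SequenceError(f"{path}: empty FASTA file (no records)")
    for entry in parsed:
        seq = clean_sequence(str(entry.seq), policy=policy)
        if not seq:
            raise SequenceError(f"record {entry.id!r}: no valid residues after cleaning")
        records.append(ProteinRecord(id=entry.id, sequence=seq))
    return Dataset(records)


def write_fasta(dataset: Dataset, path, width: int = 60) -> None:
    """Write records as FASTA (fixed line width; round-trips with read_fasta)."""
    with open(path, "w") as fh:
        for rec in dataset:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_labels(path, dataset: Dataset) -> Dataset:
    """Attach labels from a TSV (``id<TAB>label1[<TAB>label2]``) to a dataset.

    Unknown compartment strings raise :class:`LabelError`; ids absent from the
    dataset are skipped with a warning. Returns a new Dataset in the original
    record order.
    """
    index = dataset._index()
    assigned: dict[str, frozenset] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (2, 3):
                raise LabelError(
                    f"{path}:{lineno}: expected 2 or 3 tab-separated fields, "
                    f"got {len(parts)}"
                )
            rid = parts[0].strip()
            labels = frozenset(normalize_label(p) for p in parts[1:] if p.strip())
            if not labels:
                raise LabelError(f"{path}:{lineno}: no labels for id {rid!r}")
            if rid not in index:
                warnings.warn(f"{path}:{lineno}: id {rid!r} not in dataset; skipped")
                logger.warning("label row for unknown id %r skipped", rid)
                continue
            assigned[rid] = labels
    return Dataset(
        [r.with_labels(assigned[r.id]) if r.id in assigned else r for r in dataset]
    )


def write_labels(dataset: Dataset, path) -> None:
    """Write labels of labeled records as the package's label TSV dialect."""
    with open(path, "w") as fh:
        fh.write("# id\tlabel1[\tlabel2]\n")
        for rec in dataset:
            if rec.labels:
                ordered = sorted(rec.labels, key=COMPARTMENTS.index)
                fh.write(rec.id + "\t" + "\t".join(ordered) + "\n")
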