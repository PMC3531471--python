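"""Instance generation and file I/O.

Synthetic benchmarks follow the RandomSet recipe used throughout the SCSP
literature: each instance is a set of independent uniform random strings
over an alphabet of size ``q`` — the canonical configuration being eight
strings, four of length 40 and four of length 80, with ``q`` drawn from
{2, 4, 8, 16, 24}.  Real inputs arrive as FASTA (DNA or protein) or as a
plain one-sequence-per-line text format.

Text format: one sequence per line; blank lines and lines starting with
``#`` are ignored, except that a ``#alphabet: <symbols>`` header fixes
the alphabet and its symbol order (otherwise symbols are collected in
first-appearance order).  Writing emits the header, so read/write
round-trips are identity.
"""

from __future__ import annotations

import json
import logging
import random
import string as _string
from dataclasses import dataclass

from Bio import SeqIO

from .core import Alphabet, Instance

logger = logging.getLogger(__name__)

__all__ = [
    "GeneratorSpec",
    "default_alphabet",
    "DNA_ALPHABET",
    "PROTEIN_ALPHABET",
    "generate_random_instance",
    "read_instance_text",
    "write_instance_text",
    "read_fasta",
    "write_solution_text",
    "write_solution_fasta",
    "write_results_json",
    "read_results_json",
]

DNA_ALPHABET = Alphabet.from_string("ACGT")
PROTEIN_ALPHABET = Alphabet.from_string("ACDEFGHIKLMNPQRSTVWY")

_SYNTHETIC_SYMBOLS = _string.ascii_lowercase + _string.ascii_uppercase + _string.digits


def default_alphabet(q: int) -> Alphabet:
    """First ``q`` synthetic symbols (lowercase, then uppercase, then digits)."""
    if not 1 <= q <= len(_SYNTHETIC_SYMBOLS):
        raise ValueError(f"alphabet size must be in 1..{len(_SYNTHETIC_SYMBOLS)}")
    return Alphabet.from_string(_SYNTHETIC_SYMBOLS[:q])


@dataclass(frozen=True)
class GeneratorSpec:
    """Recipe for one seeded random instance."""

    alphabet_size: int
    lengths: tuple[int, ...]
    seed: int

    def __post_init__(self) -> None:
        if self.alphabet_size < 1:
            raise ValueError("alphabet_size must be >= 1")
        lengths = tuple(self.lengths)
        if not lengths or any(n < 1 for n in lengths):
            raise ValueError("every string length must be >= 1")
        object.__setattr__(self, "lengths", lengths)


def generate_random_instance(spec: GeneratorSpec,
                             instance_id: str | None = None) -> Instance:
    """I.i.d. uniform random strings; identical spec gives identical instance."""
    alphabet = default_alphabet(spec.alphabet_size)
    rng = random.Random(spec.seed)
    strings = tuple(
        "".join(rng.choice(alphabet.symbols) for _ in range(n))
        for n in spec.lengths
    )
    if instance_id is None:
        instance_id = f"rand_q{spec.alphabet_size}_s{spec.seed}"
    return Instance(alphabet, strings, id=instance_id)


def read_instance_text(path) -> Instance:
    """Parse the plain-text instance format (see module docstring)."""
    declared: Alphabet | None = None
    strings: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.lower().startswith("alphabet:"):
                    declared = Alphabet.from_string(
                        body.split(":", 1)[1].strip())
                continue
            strings.append(line)
    if not strings:
        raise ValueError(f"no sequences found in {path}")
    if declared is None:
        seen: list[str] = []
        for s in strings:
            for ch in s:
                if ch not in seen:
                    seen.append(ch)
        declared = Alphabet(tuple(seen))
    return Instance(declared, tuple(strings), id=str(path))


def write_instance_text(inst: Instance, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#alphabet: {''.join(inst.alphabet.symbols)}\n")
        for s in inst.strings:
            fh.write(s + "\n")


def read_fasta(path, kind: str | None = None) -> Instance:
    """One instance string per FASTA record, upper-cased, order preserved.

    ``kind`` selects the declared alphabet: ``"dna"`` (ACGT, warn on
    other symbols, which are appended), ``"protein"`` (20 letters), or
    ``None`` to infer symbols in first-appearance order.  Empty records
    are dropped with a warning, matching the instance-construction policy.
    """
    seqs: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        s = str(rec.seq).upper()
        if not s:
            logger.warning("dropping empty FASTA record %s", rec.id)
            continue
        seqs.append(s)
    if not seqs:
        raise ValueError(f"no non-empty records in {path}")
    observed: list[str] = []
    for s in seqs:
        for ch in s:
            if ch not in observed:
                observed.append(ch)
    if kind == "dna":
        extra = [ch for ch in observed if ch not in DNA_ALPHABET.symbols]
        if extra:
            logger.warning("DNA file %s contains non-ACGT symbols: %s",
                           path, "".join(extra))
        alphabet = Alphabet(DNA_ALPHABET.symbols + tuple(extra))
    elif kind == "protein":
        extra = [ch for ch in observed if ch not in PROTEIN_ALPHABET.symbols]
        alphabet = Alphabet(PROTEIN_ALPHABET.symbols + tuple(extra))
    elif kind is None:
        alphabet = Alphabet(tuple(observed))
    else:
        raise ValueError(f"unknown kind {kind!r}")
    return Instance(alphabet, tuple(seqs), id=str(path))


def write_solution_text(seq: str, path) -> None:
    with open(path, "w") as fh:
        fh.write(seq + "\n")


def write_solution_fasta(seq: str, path, record_id: str = "supersequence") -> None:
    with open(path, "w") as fh:
        fh.write(f">{record_id}\n")
        for i in range(0, len(seq), 70):
            fh.write(seq[i:i + 70] + "\n")


def write_results_json(records: list[dict], path) -> None:
    """One JSON record per run: instance_id, algorithm, seed, length, elapsed_sec, params."""
    with open(path, "w") as fh:
        json.dump(records, fh, indent=1)
        fh.write("\n")


def read_results_json(path) -> list[dict]:
    with open(path) as fh:
        records = json.load(fh)
    if not isinstance(records, list):
        raise ValueError("results file must hold a JSON list of run records")
    return records
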