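"""Synthetic CDR3 repertoires, antigen peptide sets, pretraining corpora and
labeled binding datasets.

The generator emulates the statistical shape of the repertoires that
peptide:TCR binding models pretrain on: an unpaired CDR3beta-like repertoire
(8-20 residues, canonical 'C'...'F' termini, interior residues i.i.d. from a
background amino-acid distribution) and an MHC-I-like antigen peptide set
(8-11 residues).  Pretraining corpora pair antigens with CDR3s either once
(static) or freshly every epoch; single-sequence corpora omit the antigen.
Labeled finetuning datasets carry a planted, learnable binding rule, with
negatives produced by re-pairing the members of positive pairs — the standard
mismatching construction for putative non-binders.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

from .encoding import AMINO_ACIDS

#: Background amino-acid frequencies (vertebrate proteome averages), order ACDE...WY.
NATURAL_FREQUENCIES = np.array(
    [
        0.0826, 0.0137, 0.0546, 0.0672, 0.0386, 0.0708, 0.0227, 0.0593, 0.0580,
        0.0965, 0.0241, 0.0406, 0.0474, 0.0393, 0.0553, 0.0660, 0.0535, 0.0687,
        0.0110, 0.0292,
    ]
)
NATURAL_FREQUENCIES = NATURAL_FREQUENCIES / NATURAL_FREQUENCIES.sum()


class ConfigurationError(ValueError):
    """A dataset spec or rule field is invalid; the message names the field."""


class CapacityError(RuntimeError):
    """The sequence pools cannot supply the requested number of labeled pairs."""


class ParseError(ValueError):
    """Malformed FASTA/CSV content; the message carries the offending location."""


class Role(str, Enum):
    ANTIGEN = "antigen"
    CDR3 = "cdr3"


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    residues: str
    role: Role

    def __post_init__(self):
        if not self.residues:
            raise ConfigurationError(f"record {self.id!r}: residues must be non-empty")
        bad = set(self.residues) - set(AMINO_ACIDS)
        if bad:
            raise ConfigurationError(
                f"record {self.id!r}: residues outside the 20-letter alphabet: {sorted(bad)}"
            )


class RuleKind(str, Enum):
    SHARED_KMER = "shared_kmer"
    POSITION_MATCH = "position_match"
    RANDOM = "random"


@dataclass(frozen=True)
class BindingRule:
    """Planted ground-truth binding rule for synthetic labeled datasets.

    shared_kmer    — pair binds iff antigen and CDR3 interior share a k-mer.
    position_match — pair binds iff >= params["min_matches"] aligned positions agree.
    random         — labels independent of sequence content (no-signal null),
                     decided by a seeded hash with P(bind) = params["p"] (default 0.5).
    """

    kind: RuleKind = RuleKind.SHARED_KMER
    k: int = 3
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.k < 1:
            raise ConfigurationError(f"binding_rule.k must be >= 1, got {self.k}")

    def evaluate(self, antigen: SequenceRecord, cdr3: SequenceRecord) -> bool:
        if self.kind == RuleKind.SHARED_KMER:
            interior = cdr3.residues[1:-1]
            if len(antigen.residues) < self.k or len(interior) < self.k:
                return False
            ag_kmers = {antigen.residues[i : i + self.k] for i in range(len(antigen.residues) - self.k + 1)}
            return any(interior[i : i + self.k] in ag_kmers for i in range(len(interior) - self.k + 1))
        if self.kind == RuleKind.POSITION_MATCH:
            min_matches = int(self.params.get("min_matches", 2))
            n = min(len(antigen.residues), len(cdr3.residues))
            matches = sum(antigen.residues[i] == cdr3.residues[i] for i in range(n))
            return matches >= min_matches
        if self.kind == RuleKind.RANDOM:
            p = float(self.params.get("p", 0.5))
            salt = int(self.params.get("salt", 0))
            digest = hashlib.blake2b(
                f"{salt}|{antigen.residues}|{cdr3.residues}".encode(), digest_size=8
            ).digest()
            return int.from_bytes(digest, "big") / 2**64 < p
        raise ConfigurationError(f"unknown rule kind {self.kind!r}")


@dataclass(frozen=True)
class SyntheticDatasetSpec:
    """Parameters of the synthetic repertoire generator.

    CDR3s are assembled VDJ-style from a small pool of V-like prefixes
    (starting 'C') and J-like suffixes (ending 'F') joined by an i.i.d.
    insert, emulating the strong fragment redundancy of real repertoires that
    makes them learnable by MLM.  Antigens are drawn from a small set of
    epitope-like motifs with a few i.i.d. variable positions.  Setting the
    fragment/motif counts to 0 disables the template structure and yields
    fully i.i.d. interiors (maximum-entropy sequences).
    """

    n_cdr3: int = 200
    n_antigen: int = 100
    cdr3_length_range: tuple[int, int] = (8, 20)
    antigen_length_range: tuple[int, int] = (8, 11)
    residue_frequencies: np.ndarray = field(default_factory=lambda: NATURAL_FREQUENCIES.copy())
    binding_rule: BindingRule = field(default_factory=BindingRule)
    n_v_fragments: int = 8
    n_j_fragments: int = 6
    n_antigen_motifs: int = 10
    n_antigen_variable: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.n_cdr3 <= 0:
            raise ConfigurationError(f"n_cdr3 must be > 0, got {self.n_cdr3}")
        if self.n_antigen <= 0:
            raise ConfigurationError(f"n_antigen must be > 0, got {self.n_antigen}")
        for name, (lo, hi) in (
            ("cdr3_length_range", self.cdr3_length_range),
            ("antigen_length_range", self.antigen_length_range),
        ):
            if not (0 < lo <= hi):
                raise ConfigurationError(f"{name} must satisfy 0 < min <= max, got ({lo}, {hi})")
        if self.cdr3_length_range[0] < 3:
            raise ConfigurationError("cdr3_length_range min must be >= 3 (C + interior + F)")
        freqs = np.asarray(self.residue_frequencies, dtype=float)
        if freqs.shape != (20,):
            raise ConfigurationError("residue_frequencies must be a 20-vector")
        if (freqs < 0).any():
            raise ConfigurationError("residue_frequencies must be nonnegative")
        if abs(freqs.sum() - 1.0) > 1e-9:
            raise ConfigurationError(f"residue_frequencies must sum to 1, got {freqs.sum()!r}")
        object.__setattr__(self, "residue_frequencies", freqs)
        if self.binding_rule.k > self.antigen_length_range[0]:
            raise ConfigurationError(
                "binding_rule.k exceeds the minimum antigen length "
                f"({self.binding_rule.k} > {self.antigen_length_range[0]})"
            )
        for name in ("n_v_fragments", "n_j_fragments", "n_antigen_motifs", "n_antigen_variable"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.n_antigen_variable > self.antigen_length_range[0]:
            raise ConfigurationError(
                "n_antigen_variable exceeds the minimum antigen length"
            )
        if (self.n_v_fragments > 0) != (self.n_j_fragments > 0):
            raise ConfigurationError(
                "n_v_fragments and n_j_fragments must both be 0 (iid mode) or both positive"
            )
        if self.n_v_fragments > 0 and self.cdr3_length_range[0] < _J_FRAGMENT_LEN + 2:
            raise ConfigurationError(
                f"cdr3_length_range min must be >= {_J_FRAGMENT_LEN + 2} in template mode"
            )

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_cdr3": self.n_cdr3,
                "n_antigen": self.n_antigen,
                "cdr3_length_range": list(self.cdr3_length_range),
                "antigen_length_range": list(self.antigen_length_range),
                "residue_frequencies": [float(f) for f in self.residue_frequencies],
                "binding_rule": {
                    "kind": self.binding_rule.kind.value,
                    "k": self.binding_rule.k,
                    "params": self.binding_rule.params,
                },
                "n_v_fragments": self.n_v_fragments,
                "n_j_fragments": self.n_j_fragments,
                "n_antigen_motifs": self.n_antigen_motifs,
                "n_antigen_variable": self.n_antigen_variable,
                "seed": self.seed,
            },
            indent=2,
        )


@dataclass(frozen=True)
class LabeledPair:
    antigen: SequenceRecord
    cdr3: SequenceRecord
    label: int

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ConfigurationError(f"label must be 0 or 1, got {self.label!r}")


class CorpusMode(str, Enum):
    STATIC_PAIRED = "static_paired"
    REPAIR_PER_EPOCH = "repair_per_epoch"
    CDR3_ONLY = "cdr3_only"


@dataclass(frozen=True)
class PretrainCorpus:
    """Unlabeled pretraining samples drawn from antigen and CDR3 pools.

    ``pairs_for_epoch(e)`` yields one (antigen-or-None, cdr3) sample per CDR3.
    In ``repair_per_epoch`` mode the antigen attached to each CDR3 is re-drawn
    independently each epoch (deterministically from (seed, e)); in
    ``static_paired`` mode one pairing is drawn once and reused; in
    ``cdr3_only`` mode samples carry no antigen portion.
    """

    mode: CorpusMode
    antigens: tuple[SequenceRecord, ...]
    cdr3s: tuple[SequenceRecord, ...]
    seed: int = 0

    def __len__(self) -> int:
        return len(self.cdr3s)

    def pairs_for_epoch(self, epoch: int) -> list[tuple[Optional[SequenceRecord], SequenceRecord]]:
        if self.mode == CorpusMode.CDR3_ONLY:
            return [(None, c) for c in self.cdr3s]
        if self.mode == CorpusMode.STATIC_PAIRED:
            rng = np.random.default_rng(np.random.SeedSequence([self.seed, 0]))
        else:
            rng = np.random.default_rng(np.random.SeedSequence([self.seed, int(epoch)]))
        idx = rng.integers(0, len(self.antigens), size=len(self.cdr3s))
        return [(self.antigens[i], c) for i, c in zip(idx, self.cdr3s)]


def _draw_residues(rng: np.random.Generator, n: int, freqs: np.ndarray) -> str:
    letters = rng.choice(list(AMINO_ACIDS), size=n, p=freqs)
    return "".join(letters)


_V_FRAGMENT_LEN = 5   # 'C' + 4 residues
_J_FRAGMENT_LEN = 6   # 5 residues + 'F'


def generate_repertoire(
    spec: SyntheticDatasetSpec,
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Generate antigen and CDR3 pools; byte-identical across runs for one spec.

    CDR3s carry the canonical CDR3beta signature — they start with 'C' and
    end with 'F'.  In template mode (the default) each CDR3 is a V-like
    prefix + i.i.d. insert + J-like suffix; short CDR3s truncate the prefix
    so the 'C'/'F' termini are always preserved.  Antigens are drawn from
    ``n_antigen_motifs`` epitope-like motifs whose ``n_antigen_variable``
    positions are re-drawn i.i.d. per peptide.  With the template counts set
    to 0, interiors and peptides are fully i.i.d. draws from
    ``spec.residue_frequencies``.
    """
    freqs = spec.residue_frequencies

    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    lo, hi = spec.antigen_length_range
    motifs: list[tuple[str, list[int]]] = []
    if spec.n_antigen_motifs > 0:
        for _ in range(spec.n_antigen_motifs):
            length = int(rng.integers(lo, hi + 1))
            template = _draw_residues(rng, length, freqs)
            variable = sorted(
                int(v) for v in rng.choice(length, size=min(spec.n_antigen_variable, length),
                                           replace=False)
            )
            motifs.append((template, variable))
    antigens = []
    for i in range(spec.n_antigen):
        if motifs:
            template, variable = motifs[int(rng.integers(len(motifs)))]
            residues = list(template)
            for pos in variable:
                residues[pos] = _draw_residues(rng, 1, freqs)
            seq = "".join(residues)
        else:
            seq = _draw_residues(rng, int(rng.integers(lo, hi + 1)), freqs)
        antigens.append(SequenceRecord(id=f"antigen_{i:05d}", residues=seq, role=Role.ANTIGEN))

    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    lo, hi = spec.cdr3_length_range
    v_pool = ["C" + _draw_residues(rng, _V_FRAGMENT_LEN - 1, freqs)
              for _ in range(spec.n_v_fragments)]
    j_pool = [_draw_residues(rng, _J_FRAGMENT_LEN - 1, freqs) + "F"
              for _ in range(spec.n_j_fragments)]
    cdr3s = []
    for i in range(spec.n_cdr3):
        length = int(rng.integers(lo, hi + 1))
        if v_pool:
            v = v_pool[int(rng.integers(len(v_pool)))]
            j = j_pool[int(rng.integers(len(j_pool)))]
            if length >= len(v) + len(j):
                insert = _draw_residues(rng, length - len(v) - len(j), freqs)
                seq = v + insert + j
            else:
                # short chain: truncate the V fragment, keep the full J end
                seq = v[: length - len(j)] + j
        else:
            seq = "C" + _draw_residues(rng, length - 2, freqs) + "F"
        cdr3s.append(SequenceRecord(id=f"cdr3_{i:05d}", residues=seq, role=Role.CDR3))
    return antigens, cdr3s


def build_pretrain_corpus(
    antigens: list[SequenceRecord],
    cdr3s: list[SequenceRecord],
    mode: CorpusMode | str,
    seed: int,
) -> PretrainCorpus:
    mode = CorpusMode(mode)
    if not cdr3s:
        raise ConfigurationError("cdr3s must be non-empty")
    if mode != CorpusMode.CDR3_ONLY and not antigens:
        raise ConfigurationError(f"antigens must be non-empty in {mode.value} mode")
    if mode == CorpusMode.CDR3_ONLY:
        antigens = []
    return PretrainCorpus(mode=mode, antigens=tuple(antigens), cdr3s=tuple(cdr3s), seed=seed)


def build_finetune_dataset(
    antigens: list[SequenceRecord],
    cdr3s: list[SequenceRecord],
    rule: BindingRule,
    n_positive: int,
    neg_ratio: float = 1.0,
    seed: int = 0,
) -> list[LabeledPair]:
    """Labeled binding pairs: rule-true positives plus mismatch negatives.

    Negatives are formed by re-pairing antigens and CDR3s that occur in the
    positive set, such that no negative combination appears among the
    positives and the rule evaluates false on it.
    """
    if n_positive <= 0:
        raise ConfigurationError(f"n_positive must be > 0, got {n_positive}")
    if neg_ratio <= 0:
        raise ConfigurationError(f"neg_ratio must be > 0, got {neg_ratio}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))

    # Scan the pool cross product in a seeded random order, keeping rule-true pairs.
    n_a, n_c = len(antigens), len(cdr3s)
    order = rng.permutation(n_a * n_c)
    positives: list[LabeledPair] = []
    for flat in order:
        a, c = antigens[flat // n_c], cdr3s[flat % n_c]
        if rule.evaluate(a, c):
            positives.append(LabeledPair(antigen=a, cdr3=c, label=1))
            if len(positives) == n_positive:
                break
    if len(positives) < n_positive:
        raise CapacityError(
            f"pools yield only {len(positives)} rule-positive pairs; "
            f"{n_positive} requested — enlarge the pools or relax the rule"
        )

    positive_keys = {(p.antigen.residues, p.cdr3.residues) for p in positives}
    pos_antigens = [p.antigen for p in positives]
    pos_cdr3s = [p.cdr3 for p in positives]

    n_negative = round(neg_ratio * n_positive)
    negatives: list[LabeledPair] = []
    neg_keys: set[tuple[str, str]] = set()
    attempts = 0
    max_attempts = 200 * n_negative
    while len(negatives) < n_negative:
        attempts += 1
        if attempts > max_attempts:
            raise CapacityError(
                f"could not assemble {n_negative} mismatch negatives after "
                f"{max_attempts} re-pairing draws ({len(negatives)} found)"
            )
        a = pos_antigens[int(rng.integers(len(pos_antigens)))]
        c = pos_cdr3s[int(rng.integers(len(pos_cdr3s)))]
        key = (a.residues, c.residues)
        if key in positive_keys or key in neg_keys or rule.evaluate(a, c):
            continue
        neg_keys.add(key)
        negatives.append(LabeledPair(antigen=a, cdr3=c, label=0))
    return positives + negatives


# ---------------------------------------------------------------------------
# FASTA / CSV input-output


def write_fasta(records: list[SequenceRecord], path: str | Path) -> None:
    bio = [
        _BioRecord(Seq(r.residues), id=r.id, description=f"role={r.role.value}")
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


def read_fasta(path: str | Path, default_role: Role | None = None) -> list[SequenceRecord]:
    """Read sequence records; lowercase residues are uppercased, ambiguity
    codes ('X', 'B', 'Z', ...) are rejected."""
    records = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        residues = str(rec.seq).upper()
        role = default_role
        for tok in rec.description.split():
            if tok.startswith("role="):
                try:
                    role = Role(tok[len("role="):])
                except ValueError:
                    raise ParseError(
                        f"{path}: record #{i} ({rec.id}): unknown role {tok[len('role='):]!r}"
                    ) from None
        if role is None:
            raise ParseError(f"{path}: record #{i} ({rec.id}): missing role annotation")
        bad = set(residues) - set(AMINO_ACIDS)
        if bad:
            raise ParseError(
                f"{path}: record #{i} ({rec.id}): residues outside the 20-letter "
                f"alphabet: {sorted(bad)}"
            )
        if not residues:
            raise ParseError(f"{path}: record #{i} ({rec.id}): empty sequence")
        records.append(SequenceRecord(id=rec.id, residues=residues, role=role))
    return records


PAIRS_CSV_HEADER = ["antigen", "cdr3", "label"]


def write_pairs_csv(pairs: list[LabeledPair], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(PAIRS_CSV_HEADER)
        for p in pairs:
            writer.writerow([p.antigen.residues, p.cdr3.residues, p.label])


def read_pairs_csv(path: str | Path) -> list[LabeledPair]:
    pairs = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file") from None
        if header != PAIRS_CSV_HEADER:
            raise ParseError(f"{path}: line 1: expected header {PAIRS_CSV_HEADER}, got {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 3:
                raise ParseError(f"{path}: line {lineno}: expected 3 columns, got {len(row)}")
            antigen_seq, cdr3_seq, label_str = row
            if label_str not in ("0", "1"):
                raise ParseError(f"{path}: line {lineno}: label must be 0 or 1, got {label_str!r}")
            try:
                pairs.append(
                    LabeledPair(
                        antigen=SequenceRecord(
                            id=f"antigen_l{lineno}", residues=antigen_seq.upper(), role=Role.ANTIGEN
                        ),
                        cdr3=SequenceRecord(
                            id=f"cdr3_l{lineno}", residues=cdr3_seq.upper(), role=Role.CDR3
                        ),
                        label=int(label_str),
                    )
                )
            except ConfigurationError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
    return pairs
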