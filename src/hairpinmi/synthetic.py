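"""Synthetic hairpin benchmark generator.

Positives emulate the stem-loop geometry of pre-miRNA precursors: a random
5' arm, a short terminal loop, and a 3' arm reverse-complementary to the 5'
arm, perturbed by G-U wobble pairs and single-base bulges, flanked by random
unpaired tails. Negatives are pseudo-hairpin stand-ins: either
dinucleotide-preserving shuffles of the positives (the principled default —
mono- and di-nucleotide composition is conserved exactly, so a classifier
must rely on structural signal) or i.i.d. sequences GC-matched to the
positives.

All randomness flows from a single integer seed through named substreams, so
a benchmark is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import folding
from .seqio import (
    LabeledRecord,
    RnaSequence,
    write_fasta,
    write_labels,
    write_vienna,
)

COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
#: wobble partner where one exists (G-U pairs)
WOBBLE = {"G": "U", "U": "G"}

NUCLEOTIDES = "ACGU"


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings.

    ``stem_fraction`` is the fraction of the total length occupied by *each*
    stem arm (default 0.4, i.e. ~80% of the molecule is stem and the rest is
    the terminal loop — the geometry of a typical pre-miRNA precursor, which
    is nearly all stem with a small loop). ``wobble_rate`` is the per-pair
    probability of a G-U wobble replacing the Watson-Crick partner;
    ``bulge_rate`` the per-stem-position probability of an unpaired
    single-base insertion in the 3' arm.
    """

    n_pos: int = 50
    n_neg: int = 50
    length_range: tuple[int, int] = (60, 120)
    stem_fraction: float = 0.4
    wobble_rate: float = 0.1
    bulge_rate: float = 0.05
    loop_min: int = 4
    negative_mode: str = "shuffle"  # or "random-gc-matched"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("stem_fraction", "wobble_rate", "bulge_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.length_range
        if lo < 20 or hi < lo:
            raise ValueError(f"invalid length range {self.length_range} (min 20)")
        arm = round(self.stem_fraction * lo)
        if 2 * arm + self.loop_min > lo:
            raise ValueError(
                "stem_fraction/loop_min leave no room at the minimum length"
            )
        if self.negative_mode not in ("shuffle", "random-gc-matched"):
            raise ValueError(f"unknown negative mode {self.negative_mode!r}")

    def rng(self, salt: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, salt])


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(NUCLEOTIDES), size=n))


def _make_hairpin(cfg: SyntheticConfig, rng: np.random.Generator) -> str:
    L = int(rng.integers(cfg.length_range[0], cfg.length_range[1] + 1))
    arm_len = max(2, round(cfg.stem_fraction * L))
    arm5 = list(_random_seq(rng, arm_len))

    # per-base partner groups: WC (or wobble) partner plus optional bulge
    groups: list[str] = []
    for base in arm5:
        if base in WOBBLE and rng.random() < cfg.wobble_rate:
            g = WOBBLE[base]
        else:
            g = COMPLEMENT[base]
        if rng.random() < cfg.bulge_rate:
            g += _random_seq(rng, 1)  # unpaired bulge insertion
        groups.append(g)

    # bulges lengthen the 3' arm; trim outer stem pairs so the record lands
    # exactly on the drawn length L
    while len(arm5) > 2 and len(arm5) + sum(map(len, groups)) + cfg.loop_min > L:
        arm5.pop(0)
        groups.pop(0)

    arm3 = "".join(groups)[::-1]
    loop_len = max(cfg.loop_min, L - len(arm5) - len(arm3))
    return "".join(arm5) + _random_seq(rng, loop_len) + arm3


def generate_positive(cfg: SyntheticConfig) -> list[LabeledRecord]:
    """Hairpin-like positive records, deterministic in ``cfg.seed``."""
    rng = cfg.rng(1)
    return [
        LabeledRecord(
            sequence=RnaSequence(id=f"pos_{i:04d}", residues=_make_hairpin(cfg, rng)),
            label=1,
        )
        for i in range(cfg.n_pos)
    ]


def dinucleotide_shuffle(s: str, rng: np.random.Generator) -> str:
    """Uniform dinucleotide-preserving shuffle (Altschul-Erickson style).

    The sequence is viewed as an Eulerian walk on the graph whose edges are
    its adjacent-base pairs; a random Eulerian walk with the same start
    vertex preserves every ordered dinucleotide count exactly.
    """
    if len(s) < 3:
        return s
    edges: dict[str, list[str]] = {}
    for a, b in zip(s, s[1:]):
        edges.setdefault(a, []).append(b)
    first, last = s[0], s[-1]
    vertices = sorted(edges)

    while True:
        # pick a candidate final edge per vertex (except the walk's end)
        last_out: dict[str, str] = {}
        for v in vertices:
            if v == last:
                continue
            last_out[v] = edges[v][int(rng.integers(len(edges[v])))]
        # the chosen final edges must connect every vertex to the end vertex
        ok = True
        for v in last_out:
            seen = {v}
            cur = v
            while cur != last:
                cur = last_out.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break

    walk_edges: dict[str, list[str]] = {}
    for v in vertices:
        rest = list(edges[v])
        if v in last_out:
            rest.remove(last_out[v])
        rng.shuffle(rest)
        walk_edges[v] = rest + ([last_out[v]] if v in last_out else [])

    out = [first]
    cur = first
    for _ in range(len(s) - 1):
        nxt = walk_edges[cur].pop(0)
        out.append(nxt)
        cur = nxt
    return "".join(out)


def generate_negative(
    cfg: SyntheticConfig, positives: list[LabeledRecord] | None = None
) -> list[LabeledRecord]:
    """Pseudo-hairpin negative records.

    ``shuffle`` mode dinucleotide-shuffles the positive sequences (cycling
    through them if n_neg > n_pos); ``random-gc-matched`` draws i.i.d.
    sequences whose expected GC content matches the positives' mean.
    """
    rng = cfg.rng(2)
    if positives is None:
        positives = generate_positive(cfg)
    out: list[LabeledRecord] = []
    if cfg.negative_mode == "shuffle":
        for i in range(cfg.n_neg):
            src = positives[i % len(positives)].sequence.residues
            out.append(
                LabeledRecord(
                    sequence=RnaSequence(
                        id=f"neg_{i:04d}", residues=dinucleotide_shuffle(src, rng)
                    ),
                    label=0,
                )
            )
    else:
        gc = float(
            np.mean(
                [
                    (r.sequence.residues.count("G") + r.sequence.residues.count("C"))
                    / len(r.sequence)
                    for r in positives
                ]
            )
        )
        p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A, C, G, U
        lengths = [len(positives[i % len(positives)].sequence) for i in range(cfg.n_neg)]
        for i, L in enumerate(lengths):
            residues = "".join(rng.choice(list(NUCLEOTIDES), size=L, p=p))
            out.append(
                LabeledRecord(sequence=RnaSequence(id=f"neg_{i:04d}", residues=residues), label=0)
            )
    return out


def make_benchmark(
    cfg: SyntheticConfig,
    out_dir: str | Path | None = None,
    fold_backend: str = "nussinov",
) -> list[LabeledRecord]:
    """Generate positives + negatives, fold every record, and (optionally)
    write the bundle as FASTA + label table + Vienna structure file."""
    positives = generate_positive(cfg)
    negatives = generate_negative(cfg, positives)
    records = positives + negatives
    for rec in records:
        rec.structure = folding.fold(rec.sequence, backend=fold_backend)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_fasta([r.sequence for r in records], out_dir / "sequences.fasta")
        write_labels(records, out_dir / "labels.tsv")
        write_vienna([(r.sequence, r.structure) for r in records], out_dir / "structures.vienna")
    return records
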