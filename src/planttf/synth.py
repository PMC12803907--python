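"""Synthetic multi-family protein corpora with implanted conserved motifs.

Real TF families are defined by conserved DNA-binding domains embedded in
otherwise variable protein sequence, and family sizes follow a long tail. The
generator emulates exactly that signal: each family gets one random conserved
motif (pairwise Hamming distance between family motifs at least half the motif
length, so families are separable by 3-mer content); each member is an i.i.d.
background sequence with the motif implanted at a random position and each
motif residue independently corrupted with probability ``mutation_rate``.
Unlabeled background sequences carry no motif and emulate non-TF proteins.

Everything is driven by a single seed; the same configuration regenerates a
byte-identical corpus.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .seqio import STANDARD_ALPHABET, LabeledCorpus, ProteinRecord

#: Published fixed configuration used by the acceptance suite: 8 families with
#: long-tail sizes, 8-residue motifs at 5% per-residue corruption, 500 non-TF
#: background sequences, seed 1337.
ACCEPTANCE_FAMILY_SIZES = (400, 300, 200, 150, 100, 60, 40, 20)
ACCEPTANCE_SEED = 1337
ACCEPTANCE_N_BACKGROUND = 500


@dataclass
class SyntheticConfig:
    """Knobs of the generator; defaults mirror a modest long-tail TF corpus."""

    n_families: int = 6
    family_sizes: tuple[int, ...] | None = None
    motif_length: int = 8
    motifs_per_family: int = 1
    mutation_rate: float = 0.05
    length_range: tuple[int, int] = (80, 300)
    background_composition: tuple[float, ...] | None = None  # uniform if None
    n_background: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family_sizes is None:
            self.family_sizes = tuple(
                _long_tail_sizes(self.n_families, largest=200, ratio=10.0)
            )
        self.family_sizes = tuple(int(s) for s in self.family_sizes)
        if len(self.family_sizes) != self.n_families:
            raise ValueError("family_sizes length must equal n_families")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be a probability")
        if self.motif_length >= self.length_range[0]:
            raise ValueError("motif_length must be below the minimum sequence length")
        if self.background_composition is not None:
            probs = np.asarray(self.background_composition)
            if probs.size != 20 or not np.isclose(probs.sum(), 1.0):
                raise ValueError("background_composition must be 20 probabilities summing to 1")


def _long_tail_sizes(n: int, largest: int, ratio: float) -> list[int]:
    """Geometric family-size decay from ``largest`` down to ``largest/ratio``."""
    if n == 1:
        return [largest]
    decay = ratio ** (1.0 / (n - 1))
    return [max(2, int(round(largest / decay**i))) for i in range(n)]


def _random_sequence(rng: np.random.Generator, length: int, probs) -> str:
    codes = rng.choice(20, size=length, p=probs)
    return "".join(STANDARD_ALPHABET[c] for c in codes)


def _draw_motifs(
    rng: np.random.Generator, n: int, length: int, min_hamming: int
) -> list[str]:
    motifs: list[str] = []
    attempts = 0
    while len(motifs) < n:
        attempts += 1
        if attempts > 10000:
            raise RuntimeError("could not draw sufficiently distinct motifs")
        cand = _random_sequence(rng, length, None)
        if all(
            sum(a != b for a, b in zip(cand, m)) >= min_hamming for m in motifs
        ):
            motifs.append(cand)
    return motifs


def _mutate(rng: np.random.Generator, motif: str, rate: float) -> str:
    if rate <= 0:
        return motif
    out = list(motif)
    for i, ch in enumerate(out):
        if rng.random() < rate:
            # substitute uniformly among the 19 other residues
            r = int(rng.integers(19))
            if r >= STANDARD_ALPHABET.index(ch):
                r += 1
            out[i] = STANDARD_ALPHABET[r]
    return "".join(out)


def generate_corpus(config: SyntheticConfig) -> tuple[LabeledCorpus, dict]:
    """Generate a labeled motif-family corpus plus a ground-truth manifest.

    The manifest records each family's motif and every member's implant
    position. Background sequences that happen to contain a family motif as an
    exact substring are regenerated, so at ``mutation_rate=0`` the motif is a
    perfect family indicator.
    """
    rng = np.random.Generator(np.random.PCG64(config.seed))
    probs = (
        np.asarray(config.background_composition)
        if config.background_composition is not None
        else None
    )
    min_hamming = max(1, config.motif_length // 2)
    motifs = _draw_motifs(
        rng, config.n_families * config.motifs_per_family,
        config.motif_length, min_hamming,
    )
    families = [f"FAM{i + 1}" for i in range(config.n_families)]
    fam_motifs = {
        fam: motifs[i * config.motifs_per_family : (i + 1) * config.motifs_per_family]
        for i, fam in enumerate(families)
    }

    records: list[ProteinRecord] = []
    implants: dict[str, dict] = {}
    lo, hi = config.length_range
    for fam, size in zip(families, config.family_sizes):
        for m in range(size):
            seq_id = f"{fam}_{m + 1:04d}"
            length = int(rng.integers(lo, hi + 1))
            background = _random_sequence(rng, length, probs)
            motif = fam_motifs[fam][int(rng.integers(config.motifs_per_family))]
            implanted = _mutate(rng, motif, config.mutation_rate)
            pos = int(rng.integers(0, length - config.motif_length + 1))
            seq = background[:pos] + implanted + background[pos + config.motif_length:]
            records.append(ProteinRecord(id=seq_id, sequence=seq, family=fam))
            implants[seq_id] = {"family": fam, "motif": motif, "position": pos,
                                "implanted": implanted}

    all_motifs = [m for ms in fam_motifs.values() for m in ms]
    for b in range(config.n_background):
        seq_id = f"BG_{b + 1:05d}"
        while True:
            length = int(rng.integers(lo, hi + 1))
            seq = _random_sequence(rng, length, probs)
            if not any(m in seq for m in all_motifs):
                break
        records.append(ProteinRecord(id=seq_id, sequence=seq, family=None))

    manifest = {
        "config": asdict(config),
        "families": families,
        "motifs": fam_motifs,
        "implants": implants,
    }
    return LabeledCorpus(records), manifest


def make_acceptance_corpus(with_manifest: bool = False):
    """The fixed benchmark corpus: 8 families sized 400/300/200/150/100/60/40/20
    (1270 labeled TFs), 8-residue motifs mutated at 5%, 500 background
    sequences, seed 1337. Deterministic."""
    config = SyntheticConfig(
        n_families=len(ACCEPTANCE_FAMILY_SIZES),
        family_sizes=ACCEPTANCE_FAMILY_SIZES,
        motif_length=8,
        mutation_rate=0.05,
        n_background=ACCEPTANCE_N_BACKGROUND,
        seed=ACCEPTANCE_SEED,
    )
    corpus, manifest = generate_corpus(config)
    return (corpus, manifest) if with_manifest else corpus
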