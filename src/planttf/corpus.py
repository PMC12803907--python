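"""Stratified splitting and balanced per-family binary training subsets.

Family sizes in curated TF corpora follow a long tail (a few families with
tens of thousands of members, many with barely a hundred), so neither over-
nor under-sampling is attractive. Instead each family gets its own balanced
binary subset: all of its (training) members as class 1, and an equal number
of class-0 sequences drawn from the remaining families proportionally to their
sizes, with largest-remainder rounding of the quotas.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .seqio import LabeledCorpus

logger = logging.getLogger(__name__)


def _family_rng(seed: int, family: str, purpose: str = "") -> np.random.Generator:
    """RNG stream derived from (master seed, family name); stable across runs.

    Using a per-family derived stream means adding or removing one family does
    not reshuffle the draws of the others.
    """
    digest = hashlib.sha256(f"{purpose}:{family}".encode()).digest()
    key = int.from_bytes(digest[:8], "little")
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, key])))


@dataclass
class SplitSpec:
    """A stratified train/test partition of the labeled ids."""

    train_ids: list[str]
    test_ids: list[str]
    fraction: float
    seed: int
    stratify_by: str = "family"

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__))

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitSpec":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class BinarySubset:
    """One family's balanced binary training set (class 1 vs sampled class 0)."""

    family: str
    positive_ids: list[str]
    negative_ids: list[str]
    seed: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__))


def stratified_split(
    corpus: LabeledCorpus, test_fraction: float, seed: int
) -> SplitSpec:
    """Per-family random split: ``round(test_fraction * family_size)`` records
    to test, at least one record always kept in train. Deterministic per seed.

    Unlabeled records are not part of the split (they are never used for
    supervised training).
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    families = corpus.families
    if not families:
        raise ValueError("corpus has no labeled families to stratify by")
    by_family: dict[str, list[str]] = {f: [] for f in families}
    for rec in corpus:
        if rec.family is not None:
            by_family[rec.family].append(rec.id)
    train_ids: list[str] = []
    test_ids: list[str] = []
    for fam in families:
        ids = by_family[fam]
        rng = _family_rng(seed, fam, "split")
        order = rng.permutation(len(ids))
        n_test = int(len(ids) * test_fraction + 0.5)
        n_test = min(n_test, len(ids) - 1)  # never empty the training side
        test_ids.extend(ids[i] for i in order[:n_test])
        train_ids.extend(ids[i] for i in order[n_test:])
    return SplitSpec(
        train_ids=train_ids, test_ids=test_ids, fraction=test_fraction, seed=seed
    )


def proportional_quotas(total: int, sizes: dict[str, int]) -> dict[str, int]:
    """Allocate ``total`` draws across donors proportionally to ``sizes``
    using largest-remainder (Hamilton) rounding; sums exactly to ``total``.
    """
    pool = sum(sizes.values())
    if pool <= 0:
        raise ValueError("no donor sequences available")
    names = list(sizes)
    exact = np.array([total * sizes[n] / pool for n in names])
    base = np.floor(exact).astype(int)
    remainder = exact - base
    short = total - int(base.sum())
    # Largest fractional parts get the leftover units; ties break by donor
    # order (first appearance), via stable argsort on -remainder.
    order = np.argsort(-remainder, kind="stable")
    for i in order[:short]:
        base[i] += 1
    return dict(zip(names, base.tolist()))


def build_binary_subset(
    corpus: LabeledCorpus,
    family: str,
    seed: int,
    split: SplitSpec | None = None,
) -> BinarySubset:
    """Balanced binary subset for ``family``.

    Positives are all its members (restricted to the training split when one
    is given, so test sequences never leak into training). Negatives match the
    positive count, allocated across the other families by largest-remainder
    proportional quotas and sampled without replacement within each donor.

    If the target family outnumbers all other families combined, all others
    become negatives and the positives are down-sampled to match (warned).
    """
    allowed = set(split.train_ids) if split is not None else None
    members: dict[str, list[str]] = {}
    for rec in corpus:
        if rec.family is None:
            continue
        if allowed is not None and rec.id not in allowed:
            continue
        members.setdefault(rec.family, []).append(rec.id)
    if family not in members or not members[family]:
        raise ValueError(f"family {family!r} absent from corpus (or its training split)")

    positives = list(members[family])
    donors = {f: ids for f, ids in members.items() if f != family}
    pool = sum(len(v) for v in donors.values())

    if pool < len(positives):
        logger.warning(
            "family %s (%d members) larger than all others combined (%d); "
            "down-sampling positives", family, len(positives), pool,
        )
        negatives = [i for ids in donors.values() for i in ids]
        rng = _family_rng(seed, family, "pos-downsample")
        keep = rng.choice(len(positives), size=pool, replace=False)
        positives = [positives[i] for i in sorted(keep)]
        return BinarySubset(family, positives, negatives, seed)

    quotas = proportional_quotas(len(positives), {f: len(v) for f, v in donors.items()})
    negatives: list[str] = []
    for donor, ids in donors.items():
        q = quotas[donor]
        if q == 0:
            continue
        rng = _family_rng(seed, f"{family}|{donor}", "neg-sample")
        pick = rng.choice(len(ids), size=q, replace=False)
        negatives.extend(ids[i] for i in sorted(pick))
    return BinarySubset(family, positives, negatives, seed)
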