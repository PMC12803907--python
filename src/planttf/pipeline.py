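"""End-to-end training: split -> encode -> ANOVA mask -> per-family binaries
-> stacking meta-classifier, returning a ready-to-use :class:`EnsembleModel`.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import replace as dc_replace

import numpy as np

from .corpus import SplitSpec, build_binary_subset, stratified_split
from .ensemble import EnsembleModel, score_all
from .features import FeatureScaler, build_mask, default_n_features
from .kmers import apply_mask, build_vocabulary, encode_corpus
from .models import (StackerEnsemble, TrainConfig, train_binary,
                     train_stacker)
from .seqio import LabeledCorpus

logger = logging.getLogger(__name__)

DEFAULT_TEST_FRACTION = 0.2


def _holdout(
    ids: list[str], fraction: float, rng: np.random.Generator
) -> tuple[list[str], list[str]]:
    """Split ids into (train, held-out), holding out ~fraction but at least 1."""
    n_val = max(1, int(round(fraction * len(ids))))
    n_val = min(n_val, len(ids) - 1)
    order = rng.permutation(len(ids))
    held = sorted(order[:n_val])
    kept = sorted(order[n_val:])
    return [ids[i] for i in kept], [ids[i] for i in held]


def _derived_seed(master: int, tag: str) -> int:
    """Stable per-component integer seed below 2**31."""
    digest = int.from_bytes(hashlib.sha256(tag.encode()).digest()[:4], "little")
    return int(np.random.SeedSequence([master, digest]).generate_state(1)[0] % (2**31))


def train_pipeline(
    corpus: LabeledCorpus,
    k: int = 3,
    n_features: int | None = None,
    seed: int = 42,
    test_fraction: float = DEFAULT_TEST_FRACTION,
    train_config: TrainConfig | None = None,
    n_stackers: int = 3,
) -> tuple[EnsembleModel, SplitSpec]:
    """Train the full ensemble on the labeled part of ``corpus``.

    The ANOVA feature mask is computed once per k on the multi-family training
    split (unlabeled background rows are excluded); every family's binary
    classifier and the stacker share it. All randomness derives from ``seed``.
    """
    labeled = corpus.labeled()
    families = labeled.families
    if len(families) < 2:
        raise ValueError("training requires at least 2 families")

    t0 = time.time()
    split = stratified_split(labeled, test_fraction, seed)
    train_corpus = labeled.subset(split.train_ids)

    vocab = build_vocabulary(k)
    full = encode_corpus(train_corpus, vocab)
    fam_of = {rec.id: rec.family for rec in train_corpus}
    train_labels = [fam_of[i] for i in full.row_ids]
    if n_features is None:
        n_features = default_n_features(k)
    mask = build_mask(full, train_labels, n_features)
    masked = apply_mask(full, mask)
    scaler = FeatureScaler.fit(masked.values)
    scaled = scaler.transform(masked.values)
    row_index = {rid: i for i, rid in enumerate(masked.row_ids)}
    logger.info("encoded %d training sequences, mask of %d features (%.1fs)",
                masked.shape[0], len(mask), time.time() - t0)

    base_config = train_config or TrainConfig()
    binaries = []
    all_train_ids = list(masked.row_ids)
    for fam in families:
        subset = build_binary_subset(labeled, fam, seed, split=split)
        config = dc_replace(base_config, seed=_derived_seed(seed, f"binary:{fam}"))
        # Stratified 10% of the subset goes to validation, enriched with
        # corpus-wide negatives: at inference every binary scores every
        # sequence, so early stopping should reflect that distribution, not
        # just the balanced subset.
        rng = np.random.Generator(
            np.random.PCG64(_derived_seed(seed, f"val:{fam}"))
        )
        pos_tr, pos_val = _holdout(subset.positive_ids, base_config.val_fraction, rng)
        neg_tr, neg_val = _holdout(subset.negative_ids, base_config.val_fraction, rng)
        in_subset = set(subset.positive_ids) | set(subset.negative_ids)
        fam_members = {r.id for r in labeled if r.family == fam}
        outside = [
            i for i in all_train_ids if i not in in_subset and i not in fam_members
        ]
        n_extra = min(len(outside), 4 * len(subset.positive_ids))
        extra = (
            [outside[i] for i in sorted(rng.choice(len(outside), n_extra, replace=False))]
            if n_extra else []
        )
        train_ids_fam = pos_tr + neg_tr
        val_ids_fam = pos_val + neg_val + extra
        X = scaled[[row_index[i] for i in train_ids_fam]]
        y = [1] * len(pos_tr) + [0] * len(neg_tr)
        X_val = scaled[[row_index[i] for i in val_ids_fam]]
        y_val = [1] * len(pos_val) + [0] * (len(neg_val) + len(extra))
        model = train_binary(X, y, config=config, val_data=(X_val, y_val))
        model.training_meta["family"] = fam
        binaries.append(model)
        logger.info("trained binary classifier for %s (%d pos / %d neg, %d val)",
                    fam, len(pos_tr), len(neg_tr), len(val_ids_fam))

    ensemble = EnsembleModel(
        k=k, mask=mask, families=families, binaries=binaries, scaler=scaler,
        meta={"seed": seed, "test_fraction": test_fraction},
    )
    P_train = score_all(ensemble, masked)
    # Stacker inputs are probabilities in [0,1]; the heavy jitter used on
    # standardized k-mer features would drown them. The jitter scale is drawn
    # per row from U(0, 0.4) so the meta-net sees both crisp and fuzzy
    # probability vectors, and a few seeds are averaged to damp extrapolation
    # overconfidence on all-quiet rows (non-TF input).
    members = []
    for i in range(n_stackers):
        stack_config = dc_replace(
            base_config,
            seed=_derived_seed(seed, f"stacker:{i}"),
            input_noise=0.4,
            input_noise_mode="uniform",
        )
        members.append(
            train_stacker(P_train, train_labels, families, config=stack_config)
        )
    ensemble.stacker = (
        StackerEnsemble(members) if len(members) > 1 else members[0]
    )
    logger.info("trained stacker over %d families (total %.1fs)",
                len(families), time.time() - t0)
    return ensemble, split
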