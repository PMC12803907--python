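import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from planttf.features import FeatureMask
from planttf.kmers import (
    apply_mask,
    build_vocabulary,
    encode_corpus,
    kmer_frequencies,
)
from planttf.seqio import STANDARD_ALPHABET, LabeledCorpus, ProteinRecord


def naive_frequencies(sequence: str, k: int) -> dict[str, float]:
    """Independent oracle: literal substring windows, valid-window counting."""
    windows = [sequence[i : i + k] for i in range(len(sequence) - k + 1)]
    valid = [w for w in windows if all(c in STANDARD_ALPHABET for c in w)]
    if not valid:
        return {}
    return {w: valid.count(w) / len(valid) for w in set(valid)}


@pytest.mark.parametrize("k,size", [(1, 20), (2, 400), (3, 8000)])
def test_vocabulary_sizes(k, size):
    vocab = build_vocabulary(k)
    assert vocab.size == size
    assert len(vocab.kmers) == size


def test_vocabulary_order_is_lexicographic():
    vocab = build_vocabulary(2)
    assert vocab.kmers == sorted(vocab.kmers)
    assert vocab.kmers[0] == "AA"
    assert vocab.kmers[-1] == "YY"
    for i in (0, 1, 399):
        assert vocab.index(vocab.kmers[i]) == i
        assert vocab.kmer_at(i) == vocab.kmers[i]


def test_vocabulary_k_out_of_range():
    with pytest.raises(ValueError):
        build_vocabulary(0)
    with pytest.raises(ValueError):
        build_vocabulary(6)


def test_single_kmer_sequence():
    vocab = build_vocabulary(2)
    freq = kmer_frequencies("AAAA", vocab)
    assert freq[vocab.index("AA")] == 1.0
    assert freq.sum() == 1.0


def test_printed_example_window_count():
    # 27-residue fragment: L - k + 1 = 25 sliding windows of length 3
    seq = "MSTNPKPQRKTKRNTNRRPQDVKFPGG"
    vocab = build_vocabulary(3)
    freq = kmer_frequencies(seq, vocab)
    assert freq[vocab.index("MST")] == pytest.approx(1 / 25)
    assert freq.sum() == pytest.approx(1.0)


def test_sequence_shorter_than_k_gives_zero_vector():
    vocab = build_vocabulary(3)
    with pytest.warns(UserWarning, match="shorter than k"):
        freq = kmer_frequencies("MK", vocab)
    assert not freq.any()


def test_invalid_residues_excluded_from_windows():
    # permissive-mode sequences may contain X; windows touching it are invalid
    vocab = build_vocabulary(2)
    freq = kmer_frequencies("AXA", vocab)
    assert not freq.any()  # both windows touch X
    freq2 = kmer_frequencies("AAXCC", vocab)
    assert freq2[vocab.index("AA")] == pytest.approx(0.5)
    assert freq2[vocab.index("CC")] == pytest.approx(0.5)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    seq=st.text(alphabet=STANDARD_ALPHABET, min_size=1, max_size=50),
    k=st.integers(min_value=2, max_value=5),
)
def test_frequencies_match_naive_oracle(seq, k):
    import warnings

    vocab = build_vocabulary(k)
    expected = naive_frequencies(seq, k)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        freq = kmer_frequencies(seq, vocab)
    nonzero = {vocab.kmer_at(i): freq[i] for i in np.nonzero(freq)[0]}
    assert nonzero == pytest.approx(expected)
    if expected:
        assert freq.sum() == pytest.approx(1.0)


def test_encode_corpus_shape_and_alignment(small_corpus):
    corpus, _ = small_corpus
    vocab = build_vocabulary(2)
    fm = encode_corpus(corpus, vocab)
    assert fm.shape == (len(corpus), 400)
    assert fm.row_ids == corpus.ids
    sums = fm.values.sum(axis=1)
    assert np.allclose(sums, 1.0, atol=1e-9)


def test_encode_corpus_identical_sequences_identical_rows():
    corpus = LabeledCorpus(
        [ProteinRecord("a", "MKVLAGH"), ProteinRecord("b", "MKVLAGH")]
    )
    fm = encode_corpus(corpus, build_vocabulary(3))
    assert np.array_equal(fm.values[0], fm.values[1])


def test_encode_empty_corpus_errors():
    with pytest.raises(ValueError):
        encode_corpus(LabeledCorpus([]), build_vocabulary(2))


def test_encode_permutation_equivariance(small_corpus, rng):
    corpus, _ = small_corpus
    records = corpus.records[:20]
    vocab = build_vocabulary(2)
    fm = encode_corpus(records, vocab)
    perm = rng.permutation(len(records))
    fm_p = encode_corpus([records[i] for i in perm], vocab)
    assert np.array_equal(fm.values[perm], fm_p.values)


def test_sparse_encoding_for_large_k():
    import scipy.sparse as sp

    corpus = LabeledCorpus([ProteinRecord("a", "MKVLAGHMKVLAGH")])
    fm = encode_corpus(corpus, build_vocabulary(4))
    assert sp.issparse(fm.values)
    assert fm.shape == (1, 160_000)
    assert fm.values.sum() == pytest.approx(1.0)


def test_apply_mask_selects_columns_in_order():
    corpus = LabeledCorpus([ProteinRecord("a", "AACC"), ProteinRecord("b", "CCAA")])
    vocab = build_vocabulary(2)
    fm = encode_corpus(corpus, vocab)
    mask = FeatureMask(k=2, indices=[vocab.index("CC"), vocab.index("AA")],
                       scores=[2.0, 1.0], n_selected=2)
    sub = apply_mask(fm, mask)
    assert sub.shape == (2, 2)
    assert sub.masked
    assert np.array_equal(sub.values[:, 0], fm.values[:, vocab.index("CC")])


def test_apply_mask_k_mismatch_and_range():
    corpus = LabeledCorpus([ProteinRecord("a", "AACC")])
    fm = encode_corpus(corpus, build_vocabulary(2))
    with pytest.raises(ValueError, match="k="):
        apply_mask(fm, FeatureMask(k=3, indices=[0], scores=[1.0], n_selected=1))
    with pytest.raises(IndexError):
        apply_mask(fm, FeatureMask(k=2, indices=[400], scores=[1.0], n_selected=1))


def test_apply_mask_identity_preserves_values():
    corpus = LabeledCorpus([ProteinRecord("a", "MKVLAGH")])
    fm = encode_corpus(corpus, build_vocabulary(2))
    identity = FeatureMask(k=2, indices=list(range(400)),
                           scores=[0.0] * 400, n_selected=400)
    sub = apply_mask(fm, identity)
    assert np.array_equal(sub.values, fm.values)


def test_apply_mask_twice_rejected():
    corpus = LabeledCorpus([ProteinRecord("a", "MKVLAGH")])
    fm = encode_corpus(corpus, build_vocabulary(2))
    mask = FeatureMask(k=2, indices=[0, 1], scores=[1.0, 0.5], n_selected=2)
    sub = apply_mask(fm, mask)
    with pytest.raises(ValueError, match="already masked"):
        apply_mask(sub, mask)
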