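"""Conditional VAE: posterior, KL, generation, quality filters, balance
metric and the augmentation driver."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from dualscreen.corpus import LabeledText
from dualscreen.synthetic import GeneratorConfig, generate_corpus
from dualscreen.vae import (
    AugmentationReport,
    VAEConfig,
    LatentCode,
    TextVAE,
    augment_to_balance,
    bag_cosine_similarity,
    class_balance,
    filter_generated,
    kl_divergence,
    normalized_edit_distance,
    passthrough_filter,
    reparameterize,
    stem_cosine_similarity,
    _condition_id,
)


# ---------------------------------------------------------------------------
# KL divergence
# ---------------------------------------------------------------------------

def test_kl_zero_at_prior():
    assert kl_divergence(np.zeros(8), np.zeros(8)) == pytest.approx(0.0, abs=1e-12)


def test_kl_unit_mean_shift_is_half():
    mu = np.zeros(8)
    mu[0] = 1.0
    assert kl_divergence(mu, np.zeros(8)) == pytest.approx(0.5, abs=1e-12)


def test_kl_matches_closed_form_oracle(rng):
    mu = rng.normal(size=16)
    lv = rng.normal(size=16) * 0.5
    expected = 0.5 * np.sum(mu**2 + np.exp(lv) - 1.0 - lv)
    assert kl_divergence(mu, lv) == pytest.approx(expected, abs=1e-9)


def test_kl_matches_numerical_integration_1d():
    """Closed form vs numerical integral of q log(q/p) for 1-D Gaussians."""
    mu, sigma = 0.7, 1.3
    q = lambda x: norm.pdf(x, mu, sigma)
    integrand = lambda x: q(x) * (norm.logpdf(x, mu, sigma) - norm.logpdf(x, 0, 1))
    numeric, _ = quad(integrand, -12, 12)
    closed = kl_divergence(np.array([mu]), np.array([2 * np.log(sigma)]))
    assert closed == pytest.approx(numeric, abs=1e-4)


# ---------------------------------------------------------------------------
# reparameterization
# ---------------------------------------------------------------------------

def test_reparameterize_zero_variance_returns_mu(rng):
    code = LatentCode(mu=np.arange(4.0), log_var=np.full(4, -745.0))
    np.testing.assert_allclose(reparameterize(code, rng), code.mu, atol=1e-150)


def test_reparameterize_sample_mean_near_mu():
    code = LatentCode(mu=np.full(1, 2.0), log_var=np.zeros(1))
    rng = np.random.default_rng(0)
    draws = np.array([reparameterize(code, rng)[0] for _ in range(10_000)])
    assert abs(draws.mean() - 2.0) < 4 / 100  # 4 sigma / sqrt(n)


def test_reparameterize_reproducible():
    code = LatentCode(mu=np.zeros(3), log_var=np.zeros(3))
    a = reparameterize(code, np.random.default_rng(5))
    b = reparameterize(code, np.random.default_rng(5))
    np.testing.assert_array_equal(a, b)


# ---------------------------------------------------------------------------
# posterior / decoding
# ---------------------------------------------------------------------------

def test_posterior_default_dimension_is_128():
    vae = TextVAE(vocab_size=20, config=VAEConfig(), seed=0)
    code = vae.encode_posterior(np.array([[3, 4, 5]]), np.ones((1, 3)))
    assert code.mu.shape == (1, 128) and code.log_var.shape == (1, 128)


def test_posterior_deterministic_and_finite_for_extreme_inputs():
    vae = TextVAE(vocab_size=20, config=VAEConfig(latent_dim=8), seed=0)
    vae.emb.weight.data *= 1e4  # extreme embeddings
    ids, mask = np.array([[3, 4, 5, 6]]), np.ones((1, 4))
    a, b = vae.encode_posterior(ids, mask), vae.encode_posterior(ids, mask)
    np.testing.assert_array_equal(a.mu, b.mu)
    assert np.isfinite(np.exp(a.log_var)).all()


def test_generation_deterministic_and_greedy_limit():
    cfg = VAEConfig(latent_dim=8, enc_hidden=8, dec_hidden=8)
    vae = TextVAE(vocab_size=25, config=cfg, seed=1)
    z = np.random.default_rng(0).normal(size=(2, 8))
    conds = np.array([0, 8])
    lengths = np.array([6, 6])
    a = vae.generate(z, conds, lengths, np.random.default_rng(3), temperature=0.8)
    b = vae.generate(z, conds, lengths, np.random.default_rng(3), temperature=0.8)
    assert a == b
    g1 = vae.generate(z, conds, lengths, np.random.default_rng(1), temperature=1e-9)
    g2 = vae.generate(z, conds, lengths, np.random.default_rng(2), temperature=1e-9)
    assert g1 == g2  # greedy decoding ignores the sampling stream


def test_conditional_signal_severe_vs_mild(vae_fixture):
    """Decoding the same latent draws under a severe vs mild condition
    yields more distress vocabulary for the severe condition."""
    corpus, config, vae, tok = vae_fixture
    inv = {i: w for w, i in tok.vocab.items()}
    rng = np.random.default_rng(0)
    z = rng.normal(size=(500, config.latent_dim))
    lengths = np.full(500, 15)
    stems = {"sad", "hopeless", "crying", "worthless", "empty", "numb", "lonely",
             "guilt", "despair", "anhedonia", "tired", "insomnia", "headache",
             "stomachache", "dizzy", "palpitations", "tense", "restless",
             "fatigue", "appetite"}

    def distress_fraction(cond):
        seqs = vae.generate(z, np.full(500, cond), lengths, np.random.default_rng(1))
        toks = [inv.get(i, "") for s in seqs for i in s]
        return np.mean([t.split("_")[0] in stems for t in toks])

    severe = distress_fraction(_condition_id("severe", "severe"))
    mild = distress_fraction(_condition_id("mild", "mild"))
    assert severe > mild


# ---------------------------------------------------------------------------
# similarity / filters
# ---------------------------------------------------------------------------

def test_bag_cosine_identity_and_disjoint():
    assert bag_cosine_similarity("a b c", "a b c") == pytest.approx(1.0)
    assert bag_cosine_similarity("a b", "c d") == 0.0
    assert bag_cosine_similarity("", "a") == 0.0


def test_stem_cosine_treats_variants_as_synonyms():
    assert stem_cosine_similarity("sad_0 tired_3", "sad_4 tired_1") == pytest.approx(1.0)


def test_edit_distance_normalised():
    assert normalized_edit_distance("a b c", "a b c") == 0.0
    assert normalized_edit_distance("a b c", "x y z") == pytest.approx(1.0)


def _orig():
    return LabeledText(record_id="o", text="sad_0 tired_0 school_0", phq9=12, gad7=11)


def test_filter_identity_passes_similarity_fails_diversity():
    cfg = VAEConfig(latent_dim=4)
    v = filter_generated(_orig(), _orig().text, ("severe", "severe"), cfg)
    assert v["similarity"] is True
    assert v["diversity"] is False
    assert v["accept"] is False


def test_filter_empty_text_fails_fluency():
    cfg = VAEConfig(latent_dim=4)
    v = filter_generated(_orig(), "", ("severe", "severe"), cfg)
    assert v["fluency"] is False and v["accept"] is False


def test_filter_similarity_boundary_is_strict():
    """Similarity exactly at the 0.7 threshold fails — the rule is
    'strictly above'."""
    cfg = VAEConfig(latent_dim=4)
    v = filter_generated(
        _orig(), "x", ("severe", "severe"), cfg,
        similarity_fn=lambda a, b: 0.7,
        fluency_fn=lambda t: 1.0,
    )
    assert v["similarity"] is False
    v2 = filter_generated(
        _orig(), "x", ("severe", "severe"), cfg,
        similarity_fn=lambda a, b: 0.7 + 1e-9,
        fluency_fn=lambda t: 1.0,
    )
    assert v2["similarity"] is True


def test_filter_missing_classifier_is_skipped_not_failed():
    cfg = VAEConfig(latent_dim=4)
    v = filter_generated(_orig(), "sad_0 tired_0 school_1", ("severe", "severe"), cfg, consistency_clf=None)
    assert v["consistency"] is None
    assert v["accept"] is True  # remaining filters pass


def test_filter_consistency_checks_condition():
    cfg = VAEConfig(latent_dim=4)
    clf = lambda text: ("severe", "severe")
    ok = filter_generated(_orig(), "sad_1 tired_1 school_1", ("severe", "severe"), cfg, consistency_clf=clf)
    bad = filter_generated(_orig(), "sad_1 tired_1 school_1", ("mild", "mild"), cfg, consistency_clf=clf)
    assert ok["consistency"] is True and bad["consistency"] is False


# ---------------------------------------------------------------------------
# class balance
# ---------------------------------------------------------------------------

def _records(strata_counts):
    out = []
    scores = {"mild": 2, "moderate": 7, "severe": 15}
    for (p, g), k in strata_counts.items():
        for i in range(k):
            out.append(LabeledText(record_id=f"{p}{g}{i}", text="t",
                                   phq9=scores[p], gad7=min(scores[g], 21)))
    return out


def test_class_balance_uniform_is_one():
    recs = _records({("mild", "mild"): 5, ("moderate", "moderate"): 5, ("severe", "severe"): 5})
    assert class_balance(recs) == pytest.approx(1.0)


def test_class_balance_single_stratum_is_zero():
    assert class_balance(_records({("mild", "mild"): 9})) == 0.0


def test_class_balance_closed_form():
    recs = _records({("mild", "mild"): 2, ("moderate", "moderate"): 1, ("severe", "severe"): 1})
    expected = (1.5 * np.log(2)) / np.log(3)
    assert class_balance(recs) == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------------------------
# augmentation driver
# ---------------------------------------------------------------------------

def test_augment_multiplier_one_is_identity(vae_fixture):
    corpus, config, vae, tok = vae_fixture
    out, report = augment_to_balance(corpus, target_multiplier=1.0, config=config, vae=vae, tokenizer=tok)
    assert out == corpus and report.n_generated == 0


def test_augment_passthrough_bookkeeping(vae_fixture):
    corpus, config, vae, tok = vae_fixture
    out, report = augment_to_balance(
        corpus, target_multiplier=2.0, config=config, vae=vae, tokenizer=tok,
        filter_fn=passthrough_filter,
    )
    assert len(out) == 2 * len(corpus)
    assert report.n_accepted == len(corpus)


def test_augment_superset_and_flags(vae_fixture):
    corpus, config, vae, tok = vae_fixture
    out, _ = augment_to_balance(
        corpus, target_multiplier=1.3, config=config, vae=vae, tokenizer=tok,
        filter_fn=passthrough_filter,
    )
    assert out[: len(corpus)] == corpus  # originals retained unmodified
    assert all(r.synthetic for r in out[len(corpus):])
    assert all(r.provenance.get("source") for r in out[len(corpus):])


def test_augment_targets_minority_and_raises_balance(vae_fixture):
    corpus, config, vae, tok = vae_fixture
    out, report = augment_to_balance(
        corpus, target_multiplier=1.5, config=config, vae=vae, tokenizer=tok,
        filter_fn=passthrough_filter,
    )
    assert report.class_balance_after > report.class_balance_before


def test_augment_with_quality_filters_still_raises_balance(vae_fixture):
    corpus, config, vae, tok = vae_fixture
    out, report = augment_to_balance(
        corpus, target_multiplier=1.5, config=config, vae=vae, tokenizer=tok,
    )
    assert report.class_balance_after >= report.class_balance_before
    assert report.n_accepted <= report.n_generated
    # scores of synthetic records equal their source records' scores
    by_id = {r.record_id: r for r in corpus}
    for r in out[len(corpus):]:
        src = by_id[r.provenance["source"]]
        assert (r.phq9, r.gad7) == (src.phq9, src.gad7)


def test_augmentation_report_invariants(vae_fixture):
    corpus, config, vae, tok = vae_fixture
    _, report = augment_to_balance(
        corpus, target_multiplier=1.2, config=config, vae=vae, tokenizer=tok,
    )
    assert isinstance(report, AugmentationReport)
    for count in report.n_passed.values():
        assert count <= report.n_generated
    assert 0.0 <= report.class_balance_before <= 1.0
    assert 0.0 <= report.class_balance_after <= 1.0
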