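"""Conditional text VAE for minority-stratum oversampling.

The encoder (bidirectional LSTM) maps a token sequence to a diagonal
Gaussian posterior q(z|x) = N(mu(x), sigma^2(x) I) in a 128-dimensional
latent space; the decoder is a GRU conditioned on the sampled latent code
and an embedding of the target (PHQ severity, GAD severity) pair, emitting
per-position categorical token distributions with temperature-scaled
sampling. Training maximises the ELBO (token-level reconstruction
likelihood + KL to the standard-normal prior) with linear KL annealing
over the first third of training to avoid posterior collapse.

Generated candidates pass four quality filters — semantic similarity to
the source text (strictly above threshold), label consistency under a
pluggable classifier, diversity against previously accepted samples
(minimum normalised edit distance), and a fluency floor — before entering
the augmented corpus. Originals are always retained unmodified.
"""

from __future__ import annotations

import difflib
import logging
import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, concat, log_softmax, no_grad
from .corpus import LabeledText, SEVERITY_LEVELS, WhitespaceTokenizer
from .nn import BiLSTM, Embedding, GRUCell, Linear, Module

log = logging.getLogger(__name__)

_SEV_INDEX = {s: i for i, s in enumerate(SEVERITY_LEVELS)}
_LOGVAR_RANGE = (-8.0, 8.0)


@dataclass
class VAEConfig:
    latent_dim: int = 128
    enc_hidden: int = 64
    dec_hidden: int = 64
    emb_dim: int = 32
    cond_dim: int = 8
    max_len: int = 32
    temperature: float = 0.8
    similarity_threshold: float = 0.7
    diversity_min: float = 0.05   # min normalised edit distance to accepted
    fluency_floor: float = 0.5
    epochs: int = 30
    batch_size: int = 32
    lr: float = 3e-3
    kl_anneal_frac: float = 1.0 / 3.0
    free_bits: float = 1.0       # nats per latent dim floored out of the KL gradient
    generation_temperature: float = 0.7  # decoding temperature for augmentation sampling
    posterior_scale: float = 0.7  # latent sampling: z = mu + scale * sigma * eps
    candidate_budget_factor: float = 12.0
    seed: int = 0

    def __post_init__(self):
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if not 0.0 < self.similarity_threshold <= 1.0:
            raise ValueError("similarity_threshold must lie in (0, 1]")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclass
class LatentCode:
    mu: np.ndarray
    log_var: np.ndarray
    z: np.ndarray | None = None


@dataclass
class AugmentationReport:
    n_original: int
    n_generated: int
    n_accepted: int
    n_passed: dict = field(default_factory=dict)
    class_balance_before: float = float("nan")
    class_balance_after: float = float("nan")
    mean_semantic_similarity: float = float("nan")
    label_consistency_rate: float = float("nan")

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _condition_id(phq_sev: str, gad_sev: str) -> int:
    return 3 * _SEV_INDEX[phq_sev] + _SEV_INDEX[gad_sev]


class TextVAE(Module):
    def __init__(self, vocab_size: int, config: VAEConfig, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.config = config
        self.vocab_size = vocab_size
        self.emb = Embedding(vocab_size, config.emb_dim, rng)
        self.encoder = BiLSTM(config.emb_dim, config.enc_hidden, rng)
        self.mu_head = Linear(2 * config.enc_hidden, config.latent_dim, rng)
        self.logvar_head = Linear(2 * config.enc_hidden, config.latent_dim, rng)
        self.cond_emb = Embedding(9, config.cond_dim, rng)  # 3x3 severity grid
        self.dec_init = Linear(config.latent_dim + config.cond_dim, config.dec_hidden, rng)
        self.dec_cell = GRUCell(config.emb_dim + config.latent_dim + config.cond_dim, config.dec_hidden, rng)
        self.out = Linear(config.dec_hidden, vocab_size, rng)

    # -- posterior -----------------------------------------------------------

    def encode_posterior_t(self, ids: np.ndarray, mask: np.ndarray) -> tuple[Tensor, Tensor]:
        h = self.encoder(self.emb(ids), mask)
        mu = self.mu_head(h)
        lv = self.logvar_head(h)
        # straight-through clamp: keeps sigma finite for extreme inputs
        lv = lv + Tensor(np.clip(lv.data, *_LOGVAR_RANGE) - lv.data)
        return mu, lv

    def encode_posterior(self, ids: np.ndarray, mask: np.ndarray) -> LatentCode:
        with no_grad():
            mu, lv = self.encode_posterior_t(ids, mask)
        return LatentCode(mu=mu.data.copy(), log_var=lv.data.copy())

    # -- decoding ------------------------------------------------------------

    def decode_logits(self, z: Tensor, cond_ids: np.ndarray, target_ids: np.ndarray) -> Tensor:
        """Teacher-forced per-position logits, shape (B, L, vocab)."""
        B, L = target_ids.shape
        cond = self.cond_emb(cond_ids)
        h = self.dec_init(concat([z, cond], axis=-1)).tanh()
        zc = concat([z, cond], axis=-1)
        logits = []
        prev = np.zeros(B, dtype=np.int64)  # BOS = pad id 0
        for t in range(L):
            x_t = concat([self.emb(prev), zc], axis=-1)
            h = self.dec_cell(x_t, h)
            logits.append(self.out(h))
            prev = target_ids[:, t]
        stacked = concat([l.reshape(B, 1, self.vocab_size) for l in logits], axis=1)
        return stacked

    def generate(
        self,
        z: np.ndarray,
        cond_ids: np.ndarray,
        lengths: np.ndarray,
        rng: np.random.Generator,
        temperature: float | None = None,
    ) -> list[list[int]]:
        """Sample token sequences (batched); temperature -> 0 is greedy."""
        temp = self.config.temperature if temperature is None else temperature
        B = z.shape[0]
        max_steps = int(np.max(lengths))
        with no_grad():
            zt = Tensor(z)
            cond = self.cond_emb(cond_ids)
            h = self.dec_init(concat([zt, cond], axis=-1)).tanh()
            zc = concat([zt, cond], axis=-1)
            prev = np.zeros(B, dtype=np.int64)
            seqs: list[list[int]] = [[] for _ in range(B)]
            for t in range(max_steps):
                x_t = concat([self.emb(prev), zc], axis=-1)
                h = self.dec_cell(x_t, h)
                logits = self.out(h).data
                if temp < 1e-6:
                    nxt = np.argmax(logits, axis=-1)
                else:
                    scaled = logits / temp
                    scaled -= scaled.max(axis=-1, keepdims=True)
                    p = np.exp(scaled)
                    p /= p.sum(axis=-1, keepdims=True)
                    nxt = np.array([rng.choice(self.vocab_size, p=p[b]) for b in range(B)])
                for b in range(B):
                    if t < lengths[b]:
                        seqs[b].append(int(nxt[b]))
                prev = nxt.astype(np.int64)
        return seqs


def reparameterize(code: LatentCode, rng: np.random.Generator) -> np.ndarray:
    """z = mu + sigma * eps with eps ~ N(0, I)."""
    sigma = np.exp(0.5 * code.log_var)
    z = code.mu + sigma * rng.standard_normal(code.mu.shape)
    code.z = z
    return z


def kl_divergence(mu, log_var):
    """Closed-form KL(N(mu, diag sigma^2) || N(0, I)) =
    0.5 * sum(mu^2 + sigma^2 - 1 - log sigma^2), summed over dimensions and
    averaged over the batch when 2-D. Works on arrays or Tensors."""
    if isinstance(mu, Tensor) or isinstance(log_var, Tensor):
        mu = mu if isinstance(mu, Tensor) else Tensor(mu)
        log_var = log_var if isinstance(log_var, Tensor) else Tensor(log_var)
        per = 0.5 * (mu * mu + log_var.exp() - 1.0 - log_var).sum(axis=-1)
        return per.mean() if len(per.shape) > 0 else per
    mu = np.asarray(mu, dtype=float)
    log_var = np.asarray(log_var, dtype=float)
    per = 0.5 * np.sum(mu**2 + np.exp(log_var) - 1.0 - log_var, axis=-1)
    return float(np.mean(per))


def vae_training_loss(
    logits: Tensor,
    target_ids: np.ndarray,
    mask: np.ndarray,
    mu: Tensor,
    log_var: Tensor,
    kl_weight: float,
    free_bits: float = 0.0,
):
    """Masked token-level reconstruction NLL + kl_weight * KL.

    With ``free_bits`` > 0 each latent dimension's batch-mean KL is floored
    at that many nats before summing, so dimensions below the floor stop
    receiving KL gradient — the standard guard against posterior collapse
    in text VAEs. At ``free_bits=0`` this is the plain ELBO with the
    closed-form diagonal-Gaussian KL.
    """
    B, L, V = logits.shape
    logp = log_softmax(logits, axis=-1)
    flat = logp.reshape(B * L, V)
    picked = flat[np.arange(B * L), target_ids.reshape(-1)]
    m = mask.reshape(-1).astype(float)
    recon = -(picked * Tensor(m)).sum() * (1.0 / B)
    if free_bits > 0.0:
        per_dim = (0.5 * (mu * mu + log_var.exp() - 1.0 - log_var)).mean(axis=0)
        kl = per_dim.clip_min(free_bits).sum()
    else:
        kl = kl_divergence(mu, log_var)
    return recon + kl_weight * kl


def train_vae(records, config: VAEConfig, tokenizer=None):
    """Fit the conditional VAE on the given (training-split) records."""
    if tokenizer is None:
        tokenizer = WhitespaceTokenizer.fit(r.text for r in records)
    rng = np.random.default_rng(config.seed)
    vae = TextVAE(tokenizer.vocab_size, config, seed=int(rng.integers(2**31 - 1)))

    enc = [tokenizer.encode(r.text)[1:][: config.max_len] for r in records]  # drop CLS
    L = max((len(e) for e in enc), default=1)
    ids = np.zeros((len(records), L), dtype=np.int64)
    mask = np.zeros((len(records), L), dtype=np.int64)
    for i, e in enumerate(enc):
        ids[i, : len(e)] = e
        mask[i, : len(e)] = 1
    conds = np.array([_condition_id(r.phq9_severity, r.gad7_severity) for r in records])

    from .training import AdamW

    opt = AdamW(vae.parameters())
    n = len(records)
    # inverse-frequency sampling: minority strata are reconstructed as well
    # as common ones, which is what conditional minority generation needs
    strata = [r.stratum for r in records]
    counts = Counter(strata)
    w = np.array([1.0 / counts[s] for s in strata])
    w /= w.sum()
    total_steps = max(1, config.epochs * math.ceil(n / config.batch_size))
    step = 0
    for epoch in range(config.epochs):
        order = rng.choice(n, size=n, replace=True, p=w)
        ep_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start: start + config.batch_size]
            mu, lv = vae.encode_posterior_t(ids[idx], mask[idx])
            eps = rng.standard_normal(mu.shape)
            z = mu + (0.5 * lv).exp() * Tensor(eps)
            logits = vae.decode_logits(z, conds[idx], ids[idx])
            kl_w = min(1.0, step / max(1.0, config.kl_anneal_frac * total_steps))
            loss = vae_training_loss(logits, ids[idx], mask[idx], mu, lv, kl_w, config.free_bits)
            vae.zero_grad()
            loss.backward()
            grads = {k: p.grad for k, p in vae.parameters().items() if p.grad is not None}
            opt.step(config.lr, grads)
            ep_loss += float(loss.data) * len(idx)
            step += 1
        log.info("VAE epoch %d loss %.3f", epoch, ep_loss / n)
    vae.eval()
    return vae, tokenizer


# ---------------------------------------------------------------------------
# quality filters
# ---------------------------------------------------------------------------

def _cosine(ca: Counter, cb: Counter) -> float:
    if not ca or not cb:
        return 0.0
    dot = sum(ca[t] * cb[t] for t in ca)
    na = math.sqrt(sum(v * v for v in ca.values()))
    nb = math.sqrt(sum(v * v for v in cb.values()))
    return dot / (na * nb)


def bag_cosine_similarity(a: str, b: str) -> float:
    """Cosine similarity between exact bag-of-token count vectors."""
    return _cosine(Counter(a.split()), Counter(b.split()))


def stem_cosine_similarity(a: str, b: str) -> float:
    """Cosine similarity over token *stems* (the part before ``_``): tokens
    in the same synonym class count as semantically equivalent. This is
    the default semantic-similarity slot for symbolic corpora; production
    use would plug in a sentence-embedding model here."""
    stem = lambda t: t.split("_", 1)[0]
    return _cosine(
        Counter(stem(t) for t in a.split()),
        Counter(stem(t) for t in b.split()),
    )


def normalized_edit_distance(a: str, b: str) -> float:
    """1 - similarity ratio of the token sequences (0 = identical)."""
    return 1.0 - difflib.SequenceMatcher(None, a.split(), b.split(), autojunk=False).ratio()


def default_fluency(text: str) -> float:
    toks = text.split()
    if len(toks) < 3:
        return 0.0
    distinct = len(set(toks)) / len(toks)
    return 1.0 if distinct >= 0.3 else 0.5 + 0.5 * distinct


def filter_generated(
    original: LabeledText,
    generated: str,
    y: tuple[str, str],
    config: VAEConfig,
    similarity_fn=stem_cosine_similarity,
    consistency_clf=None,
    fluency_fn=default_fluency,
    accepted: list[str] = (),
) -> dict:
    """Apply the four quality mechanisms. Returns per-filter booleans
    (or ``None`` when a pluggable model is missing and the filter is
    skipped) plus the overall ``accept`` decision and the similarity score.
    """
    result: dict = {}
    sim = similarity_fn(original.text, generated) if similarity_fn else None
    result["similarity_score"] = sim
    result["similarity"] = None if sim is None else sim > config.similarity_threshold
    if consistency_clf is None:
        result["consistency"] = None
        log.debug("consistency filter skipped (no classifier supplied)")
    else:
        result["consistency"] = tuple(consistency_clf(generated)) == tuple(y)
    references = [original.text, *accepted]
    dist = min((normalized_edit_distance(generated, ref) for ref in references), default=1.0)
    result["diversity_distance"] = dist
    result["diversity"] = dist >= config.diversity_min
    flu = fluency_fn(generated) if fluency_fn else None
    result["fluency_score"] = flu
    result["fluency"] = None if flu is None else flu >= config.fluency_floor
    result["accept"] = all(v for v in (result["similarity"], result["consistency"], result["diversity"], result["fluency"]) if v is not None)
    return result


def passthrough_filter(original, generated, y, config, **kw) -> dict:
    """Accept-everything filter set (bookkeeping / smoke runs)."""
    return {"similarity": None, "consistency": None, "diversity": None, "fluency": None,
            "similarity_score": None, "fluency_score": None, "accept": True}


# ---------------------------------------------------------------------------
# balance metric + augmentation driver
# ---------------------------------------------------------------------------

def class_balance(corpus) -> float:
    """Normalised entropy H(p)/log(K) of the joint severity-stratum
    distribution over the K occupied strata; 1 = perfectly uniform,
    0 = single stratum."""
    if not corpus:
        raise ValueError("corpus is empty")
    counts = Counter(r.stratum for r in corpus)
    k = len(counts)
    if k == 1:
        return 0.0
    p = np.array(list(counts.values()), dtype=float)
    p /= p.sum()
    return float(-(p * np.log(p)).sum() / np.log(k))


class BagOfWordsConsistencyClassifier:
    """Label-consistency checker: two bag-of-words logistic regressions
    predicting the PHQ and GAD severity levels, fitted on original data."""

    def __init__(self, records):
        from sklearn.feature_extraction.text import CountVectorizer
        from sklearn.linear_model import LogisticRegression

        self.vec = CountVectorizer(analyzer=lambda t: t.split())
        X = self.vec.fit_transform([r.text for r in records])
        self.clf_phq = LogisticRegression(max_iter=500)
        self.clf_gad = LogisticRegression(max_iter=500)
        self.clf_phq.fit(X, [r.phq9_severity for r in records])
        self.clf_gad.fit(X, [r.gad7_severity for r in records])

    def __call__(self, text: str) -> tuple[str, str]:
        X = self.vec.transform([text])
        return (str(self.clf_phq.predict(X)[0]), str(self.clf_gad.predict(X)[0]))


def _stratum_quotas(corpus, n_new: int) -> dict[tuple[str, str], int]:
    """Allocate the new-sample budget preferentially to the smallest
    occupied strata (waterfilling toward a uniform distribution)."""
    counts = Counter(r.stratum for r in corpus)
    keys = sorted(counts)
    quotas = {k: 0 for k in keys}
    sizes = {k: counts[k] for k in keys}
    for _ in range(n_new):
        smallest = min(keys, key=lambda k: (sizes[k] + quotas[k], k))
        quotas[smallest] += 1
    return quotas


def augment_to_balance(
    corpus,
    target_multiplier: float = 2.0,
    config: VAEConfig | None = None,
    vae: TextVAE | None = None,
    tokenizer=None,
    filter_fn=filter_generated,
    consistency_clf="auto",
    similarity_fn=stem_cosine_similarity,
):
    """Oversample under-represented severity strata with VAE-generated
    records until the accepted count reaches ``(multiplier - 1) * n`` or a
    candidate budget is exhausted.

    Originals are always retained unmodified (superset property). The VAE
    is trained in-pipeline on ``corpus`` only — callers pass the training
    split, never validation or test data.

    ``consistency_clf="auto"`` fits a bag-of-words severity classifier on
    ``corpus`` for the label-consistency filter; pass ``None`` to skip that
    filter or supply any callable ``text -> (phq_severity, gad_severity)``.
    """
    config = config or VAEConfig()
    corpus = list(corpus)
    n = len(corpus)
    if target_multiplier < 1.0:
        raise ValueError("target_multiplier must be >= 1")
    n_new = int(round((target_multiplier - 1.0) * n))
    balance_before = class_balance(corpus)
    if n_new == 0:
        return corpus, AugmentationReport(
            n_original=n, n_generated=0, n_accepted=0,
            class_balance_before=balance_before, class_balance_after=balance_before,
        )

    if vae is None:
        vae, tokenizer = train_vae(corpus, config, tokenizer)
    elif tokenizer is None:
        raise ValueError("a fitted VAE requires its tokenizer")
    if isinstance(consistency_clf, str) and consistency_clf == "auto":
        consistency_clf = (
            BagOfWordsConsistencyClassifier(corpus) if filter_fn is filter_generated else None
        )
    inv_vocab = {i: w for w, i in tokenizer.vocab.items()}
    rng = np.random.default_rng(config.seed + 7)

    by_stratum: dict[tuple[str, str], list[LabeledText]] = {}
    for r in corpus:
        by_stratum.setdefault(r.stratum, []).append(r)
    quotas = _stratum_quotas(corpus, n_new)

    augmented = list(corpus)
    accepted_texts: dict[tuple[str, str], list[str]] = {k: [] for k in quotas}
    n_generated = 0
    n_passed = Counter()
    sims, consistency_flags = [], []

    for stratum, quota in quotas.items():
        if quota == 0:
            continue
        sources = by_stratum[stratum]
        budget = int(math.ceil(quota * config.candidate_budget_factor))
        made = 0
        while made < quota and budget > 0:
            batch = min(quota - made + 4, budget, 64)
            src = [sources[int(rng.integers(len(sources)))] for _ in range(batch)]
            enc = [tokenizer.encode(r.text)[1:][: config.max_len] for r in src]
            L = max(len(e) for e in enc)
            ids = np.zeros((batch, L), dtype=np.int64)
            mask = np.zeros((batch, L), dtype=np.int64)
            for i, e in enumerate(enc):
                ids[i, : len(e)] = e
                mask[i, : len(e)] = 1
            code = vae.encode_posterior(ids, mask)
            sigma = np.exp(0.5 * code.log_var)
            z = code.mu + config.posterior_scale * sigma * rng.standard_normal(code.mu.shape)
            conds = np.full(batch, _condition_id(*stratum))
            lengths = np.array([max(3, len(e)) for e in enc])
            seqs = vae.generate(z, conds, lengths, rng, temperature=config.generation_temperature)
            for r_src, seq in zip(src, seqs):
                if made >= quota or budget <= 0:
                    break
                budget -= 1
                n_generated += 1
                text = " ".join(inv_vocab.get(i, "<unk>") for i in seq if i > 2)
                verdict = filter_fn(
                    r_src, text, stratum, config,
                    similarity_fn=similarity_fn,
                    consistency_clf=consistency_clf,
                    accepted=accepted_texts[stratum],
                ) if filter_fn is filter_generated else filter_fn(r_src, text, stratum, config)
                for key in ("similarity", "consistency", "diversity", "fluency"):
                    if verdict.get(key):
                        n_passed[key] += 1
                if verdict.get("similarity_score") is not None:
                    sims.append(verdict["similarity_score"])
                if verdict.get("consistency") is not None:
                    consistency_flags.append(bool(verdict["consistency"]))
                if not verdict["accept"]:
                    continue
                made += 1
                accepted_texts[stratum].append(text)
                augmented.append(
                    LabeledText(
                        record_id=f"aug{len(augmented):06d}",
                        text=text if text.strip() else "<unk>",
                        phq9=r_src.phq9,
                        gad7=r_src.gad7,
                        subject_id=r_src.subject_id,
                        cohort=r_src.cohort,
                        synthetic=True,
                        provenance={"source": r_src.record_id,
                                    "similarity": verdict.get("similarity_score")},
                    )
                )
        if made < quota:
            log.warning("stratum %s: accepted %d of %d before budget ran out", stratum, made, quota)

    report = AugmentationReport(
        n_original=n,
        n_generated=n_generated,
        n_accepted=len(augmented) - n,
        n_passed=dict(n_passed),
        class_balance_before=balance_before,
        class_balance_after=class_balance(augmented),
        mean_semantic_similarity=float(np.mean(sims)) if sims else float("nan"),
        label_consistency_rate=float(np.mean(consistency_flags)) if consistency_flags else float("nan"),
    )
    return augmented, report


def expand_test_set(records, multiplier: float, config: VAEConfig | None = None, **kw):
    """Explicitly labeled test-set expansion (kept separate from training
    augmentation so evaluation data never leaks into VAE training)."""
    log.warning("expanding an evaluation set with synthetic samples; metrics "
                "computed on it are not comparable to original-only metrics")
    return augment_to_balance(records, target_multiplier=multiplier, config=config, **kw)
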