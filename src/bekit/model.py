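"""Two-component editing-outcome predictor.

The predictor pairs an *efficiency* encoder (total edited fraction of a site)
with a *proportion* encoder (conditional distribution over edited outcomes);
their product gives the full outcome distribution:

    P(unedited)   = 1 - eff(site)
    P(outcome_i)  = eff(site) * proportion_i(site)

Both components are attention encoders over the protospacer plus its 4-nt PAM
context (input modes with protospacer only, or with 5-nt flanks added, are
supported for ablations).  The proportion component feeds the reference and
the candidate outcome sequence through shared-weight twin encoders and scores
the pair; scores are normalized by softmax across a site's outcomes.

Estimators follow the scikit-learn protocol (``fit``/``predict``,
``get_params``/``set_params``, fitted attributes with a trailing underscore).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .nn.autodiff import AdamW, bce_with_logits, concat, segment_softmax_xent
from .nn.encoder import EncoderConfig, MLPHead, TransformerEncoder
from .outcomes import (
    Outcome,
    OutcomeDistribution,
    apply_edits,
    enumerate_outcomes,
    per_position_efficiency,
)
from .screen import ScreenDataset
from .seqcore import TargetSite

INPUT_MODES = ("protospacer", "proto+pam", "proto+pam+flanks")
_BASE_IDS = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_ID_BASES = "ACGTN"


@dataclass(frozen=True)
class TokenizedPair:
    """Reference and outcome token sequences for one (site, outcome) pair."""

    ref_tokens: np.ndarray
    out_tokens: np.ndarray
    mode: str


def _input_sequence(site: TargetSite, protospacer: str, mode: str) -> str:
    if mode == "protospacer":
        return protospacer
    if mode == "proto+pam":
        return protospacer + site.pam_context
    if mode == "proto+pam+flanks":
        f5 = site.flank5[-5:].rjust(5, "N")
        f3 = site.flank3[1:6].ljust(5, "N")   # flank3[0] is pam_context[3]
        return f5 + protospacer + site.pam_context + f3
    raise ValueError(f"unknown input mode {mode!r}; choose from {INPUT_MODES}")


def input_length(mode: str) -> int:
    return {"protospacer": 20, "proto+pam": 24, "proto+pam+flanks": 34}[mode]


def tokenize(site: TargetSite, outcome: Outcome | None = None,
             mode: str = "proto+pam") -> TokenizedPair:
    """Tokenize a site (and optionally one of its outcomes) for the encoders."""
    ref_seq = _input_sequence(site, site.protospacer, mode)
    if outcome is None:
        out_seq = ref_seq
    else:
        for p in outcome.positions:
            if site.protospacer[p - 1] != "A":
                raise ValueError(
                    f"outcome edits position {p} but site {site.site_id} has "
                    f"{site.protospacer[p-1]!r} there"
                )
        out_seq = _input_sequence(site, outcome.sequence, mode)
    ref = np.array([_BASE_IDS[c] for c in ref_seq], dtype=np.int64)
    out = np.array([_BASE_IDS[c] for c in out_seq], dtype=np.int64)
    return TokenizedPair(ref, out, mode)


def detokenize(tokens: np.ndarray) -> str:
    return "".join(_ID_BASES[i] for i in np.asarray(tokens))


def _spearman(a, b) -> float:
    r = stats.spearmanr(a, b).statistic
    return float(r) if np.isfinite(r) else 0.0


class EfficiencyModel(RegressorMixin, BaseEstimator):
    """Attention-encoder regressor for total editing efficiency in [0, 1].

    Trained with binary cross-entropy against the observed efficiency as a
    soft label, optionally weighted by read depth.  Early stopping monitors
    validation Spearman when validation data is supplied, else training loss.
    """

    def __init__(self, input_mode: str = "proto+pam", d_model: int = 64,
                 n_heads: int = 4, n_layers: int = 2, d_ff: int = 128,
                 dropout: float = 0.1, lr: float = 1e-3, weight_decay: float = 0.01,
                 batch_size: int = 256, max_epochs: int = 30, patience: int = 5,
                 seed: int = 0):
        self.input_mode = input_mode
        self.d_model = d_model
        self.n_heads = n_heads
        self.n_layers = n_layers
        self.d_ff = d_ff
        self.dropout = dropout
        self.lr = lr
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.seed = seed

    # -- internals -------------------------------------------------------
    def _build(self, rng):
        cfg = EncoderConfig(
            vocab_size=5, max_len=input_length(self.input_mode),
            d_model=self.d_model, n_heads=self.n_heads, n_layers=self.n_layers,
            d_ff=self.d_ff, dropout=self.dropout,
        )
        self.config_ = cfg
        self.encoder_ = TransformerEncoder(cfg, rng)
        self.head_ = MLPHead(self.d_model, rng)

    def _ids(self, sites) -> np.ndarray:
        return np.stack([tokenize(s, mode=self.input_mode).ref_tokens for s in sites])

    def _all_params(self):
        p = {f"enc.{k}": v for k, v in self.encoder_.params.items()}
        p.update({f"head.{k}": v for k, v in self.head_.params.items()})
        return p

    def _forward_logits(self, ids, rng=None, train=False):
        return self.head_(self.encoder_(ids, rng, train))

    # -- sklearn surface ---------------------------------------------------
    def fit(self, X, y, sample_weight=None, validation_data=None):
        """Fit on sites X with observed efficiencies y.

        ``validation_data`` is an optional (sites, efficiencies) pair used for
        early stopping on Spearman correlation.
        """
        y = np.asarray(y, dtype=float)
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        if len(X) == 0:
            raise ValueError("empty training partition")
        rng = np.random.default_rng(self.seed)
        self._build(rng)
        ids = self._ids(X)
        w = None if sample_weight is None else np.asarray(sample_weight, float)
        opt = AdamW(self._all_params(), lr=self.lr, weight_decay=self.weight_decay)
        val_ids = val_y = None
        if validation_data is not None:
            val_sites, val_y = validation_data
            val_ids = self._ids(val_sites)
            val_y = np.asarray(val_y, float)

        self.history_ = []
        best_metric, best_state, bad = -np.inf, None, 0
        n = len(X)
        for epoch in range(self.max_epochs):
            order = rng.permutation(n)
            losses = []
            for lo in range(0, n, self.batch_size):
                idx = order[lo:lo + self.batch_size]
                logits = self._forward_logits(ids[idx], rng, train=True)
                loss = bce_with_logits(logits, y[idx], None if w is None else w[idx])
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            rec = {"epoch": epoch, "train_loss": float(np.mean(losses))}
            if val_ids is not None:
                pred = self._predict_ids(val_ids)
                rec["val_spearman"] = _spearman(pred, val_y)
                metric = rec["val_spearman"]
            else:
                metric = -rec["train_loss"]
            self.history_.append(rec)
            if metric > best_metric + 1e-6:
                best_metric, bad = metric, 0
                best_state = (self.encoder_.state_dict(), self.head_.state_dict())
            else:
                bad += 1
                if bad >= self.patience:
                    break
        if best_state is not None:
            self.encoder_.load_state_dict(best_state[0])
            self.head_.load_state_dict(best_state[1])
        self.n_epochs_ = len(self.history_)
        return self

    def _predict_ids(self, ids) -> np.ndarray:
        out = []
        for lo in range(0, len(ids), 1024):
            logits = self._forward_logits(ids[lo:lo + 1024])
            out.append(1.0 / (1.0 + np.exp(-logits.data)))
        return np.concatenate(out)

    def predict(self, X) -> np.ndarray:
        """Predicted total editing efficiency for each site, in [0, 1]."""
        if not hasattr(self, "encoder_"):
            raise ValueError("model is not fitted")
        return self._predict_ids(self._ids(X))


class ProportionModel(BaseEstimator):
    """Twin-encoder model of the conditional distribution over edited outcomes.

    The reference and each candidate outcome sequence pass through a shared
    encoder; pooled representations are concatenated and scored, and scores
    are softmax-normalized across the site's enumerated edited outcomes.
    Trained by cross-entropy against observed conditional frequencies,
    weighted by each site's edited-read count.  For adenine-rich sites the
    training pairs are subsampled (all observed outcomes plus random
    unobserved ones, ``max_outcomes_train`` total).
    """

    def __init__(self, input_mode: str = "proto+pam", d_model: int = 64,
                 n_heads: int = 4, n_layers: int = 2, d_ff: int = 128,
                 dropout: float = 0.1, lr: float = 1e-3, weight_decay: float = 0.01,
                 pairs_per_batch: int = 1024, max_epochs: int = 15, patience: int = 3,
                 max_outcomes_train: int = 32, seed: int = 0):
        self.input_mode = input_mode
        self.d_model = d_model
        self.n_heads = n_heads
        self.n_layers = n_layers
        self.d_ff = d_ff
        self.dropout = dropout
        self.lr = lr
        self.weight_decay = weight_decay
        self.pairs_per_batch = pairs_per_batch
        self.max_epochs = max_epochs
        self.patience = patience
        self.max_outcomes_train = max_outcomes_train
        self.seed = seed

    def _build(self, rng):
        cfg = EncoderConfig(
            vocab_size=5, max_len=input_length(self.input_mode),
            d_model=self.d_model, n_heads=self.n_heads, n_layers=self.n_layers,
            d_ff=self.d_ff, dropout=self.dropout,
        )
        self.config_ = cfg
        self.encoder_ = TransformerEncoder(cfg, rng)
        self.head_ = MLPHead(2 * self.d_model, rng, d_hidden=self.d_model)

    def _all_params(self):
        p = {f"enc.{k}": v for k, v in self.encoder_.params.items()}
        p.update({f"head.{k}": v for k, v in self.head_.params.items()})
        return p

    def _site_pairs(self, site, targets: dict[Outcome, float], rng):
        """Training rows for one site: (ref_ids, out_ids, target) triples."""
        edited = [o for o in enumerate_outcomes(site.protospacer) if o.is_edited]
        if not edited:
            return None
        if len(edited) > self.max_outcomes_train:
            observed = [o for o in edited if targets.get(o, 0.0) > 0]
            observed.sort(key=lambda o: -targets.get(o, 0.0))
            observed = observed[:self.max_outcomes_train]
            rest = [o for o in edited if targets.get(o, 0.0) <= 0]
            n_fill = self.max_outcomes_train - len(observed)
            fill = list(rng.choice(len(rest), size=min(n_fill, len(rest)),
                                   replace=False)) if rest and n_fill else []
            edited = observed + [rest[i] for i in fill]
        ref = tokenize(site, mode=self.input_mode).ref_tokens
        rows = [(ref, tokenize(site, o, mode=self.input_mode).out_tokens,
                 targets.get(o, 0.0)) for o in edited]
        return rows

    def _score_pairs(self, ref_ids, out_ids, rng=None, train=False):
        pooled_ref = self.encoder_(ref_ids, rng, train)
        pooled_out = self.encoder_(out_ids, rng, train)
        return self.head_(concat([pooled_ref, pooled_out], axis=-1))

    def fit(self, X, y, sample_weight=None, validation_data=None):
        """Fit on sites X with conditional outcome targets y.

        ``y`` is a sequence of ``{Outcome: conditional frequency}`` mappings
        (one per site; may be empty for sites with no edited reads, which are
        skipped).  ``sample_weight`` is typically each site's edited-read
        count.
        """
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        rng = np.random.default_rng(self.seed)
        self._build(rng)
        w = np.ones(len(X)) if sample_weight is None else np.asarray(sample_weight, float)
        usable = [(s, t, wi) for s, t, wi in zip(X, y, w) if t]
        if not usable:
            raise ValueError("no sites with edited reads to train on")
        opt = AdamW(self._all_params(), lr=self.lr, weight_decay=self.weight_decay)

        self.history_ = []
        best_metric, best_state, bad = -np.inf, None, 0
        for epoch in range(self.max_epochs):
            order = rng.permutation(len(usable))
            losses = []
            batch_rows, batch_w, n_pairs = [], [], 0
            for j in order:
                site, targets, wi = usable[j]
                rows = self._site_pairs(site, targets, rng)
                if rows is None:
                    continue
                batch_rows.append(rows)
                batch_w.append(wi)
                n_pairs += len(rows)
                if n_pairs >= self.pairs_per_batch:
                    losses.append(self._step(opt, batch_rows, batch_w, rng))
                    batch_rows, batch_w, n_pairs = [], [], 0
            if batch_rows:
                losses.append(self._step(opt, batch_rows, batch_w, rng))
            rec = {"epoch": epoch, "train_loss": float(np.mean(losses))}
            self.history_.append(rec)
            metric = -rec["train_loss"]
            if metric > best_metric + 1e-6:
                best_metric, bad = metric, 0
                best_state = (self.encoder_.state_dict(), self.head_.state_dict())
            else:
                bad += 1
                if bad >= self.patience:
                    break
        if best_state is not None:
            self.encoder_.load_state_dict(best_state[0])
            self.head_.load_state_dict(best_state[1])
        self.n_epochs_ = len(self.history_)
        return self

    def _step(self, opt, batch_rows, batch_w, rng):
        refs = np.stack([r for rows in batch_rows for r, _, _ in rows])
        outs = np.stack([o for rows in batch_rows for _, o, _ in rows])
        targets = np.array([t for rows in batch_rows for _, _, t in rows])
        seg = np.concatenate([
            np.full(len(rows), i) for i, rows in enumerate(batch_rows)
        ]).astype(np.int64)
        scores = self._score_pairs(refs, outs, rng, train=True)
        loss = segment_softmax_xent(scores, targets, seg, np.asarray(batch_w, float))
        opt.zero_grad()
        loss.backward()
        opt.step()
        return float(loss.data)

    def predict_proportions(self, site: TargetSite) -> dict[Outcome, float]:
        """Softmax-normalized proportions over all enumerated edited outcomes."""
        if not hasattr(self, "encoder_"):
            raise ValueError("model is not fitted")
        edited = [o for o in enumerate_outcomes(site.protospacer) if o.is_edited]
        if not edited:
            raise ValueError(f"site {site.site_id} has no editable adenine")
        ref = tokenize(site, mode=self.input_mode).ref_tokens
        scores = []
        for lo in range(0, len(edited), 512):
            chunk = edited[lo:lo + 512]
            outs = np.stack([tokenize(site, o, mode=self.input_mode).out_tokens
                             for o in chunk])
            refs = np.broadcast_to(ref, outs.shape)
            scores.append(self._score_pairs(refs, outs).data)
        z = np.concatenate(scores).astype(np.float64)
        z -= z.max()
        p = np.exp(z)
        p /= p.sum()
        p /= p.sum()           # second pass: exact unit sum in float64
        return {o: float(q) for o, q in zip(edited, p)}


class BedictModel:
    """Bundle of a fitted efficiency and proportion model with one tokenizer."""

    def __init__(self, efficiency: EfficiencyModel, proportion: ProportionModel | None,
                 metadata: dict | None = None):
        if proportion is not None and proportion.input_mode != efficiency.input_mode:
            raise ValueError("efficiency and proportion input modes differ")
        self.efficiency = efficiency
        self.proportion = proportion
        self.metadata = metadata or {}

    def predict_efficiency(self, site: TargetSite) -> float:
        return float(self.efficiency.predict([site])[0])

    def predict_proportions(self, site: TargetSite) -> dict[Outcome, float]:
        if self.proportion is None:
            raise ValueError("no proportion component in this bundle")
        return self.proportion.predict_proportions(site)

    def predict_distribution(self, site: TargetSite) -> OutcomeDistribution:
        eff = self.predict_efficiency(site)
        props = self.predict_proportions(site)
        outcomes = [apply_edits(site.protospacer, ())]
        q = np.array(list(props.values()), dtype=np.float64)
        q *= eff / q.sum() if q.sum() > 0 else 0.0
        outcomes.extend(props.keys())
        probs = np.concatenate([[1.0 - eff], q])
        return OutcomeDistribution(site.site_id, outcomes, probs)

    def predict_per_position(self, site: TargetSite) -> np.ndarray:
        return per_position_efficiency(self.predict_distribution(site))

    # -- checkpointing ---------------------------------------------------
    def save(self, path) -> None:
        """Single-file checkpoint: weights + config + metadata (versioned)."""
        arrays = {}
        meta = {
            "schema": 1,
            "metadata": self.metadata,
            "efficiency": {"params": self.efficiency.get_params(),
                           "history": getattr(self.efficiency, "history_", [])},
        }
        for k, v in self.efficiency.encoder_.state_dict().items():
            arrays[f"eff.enc.{k}"] = v
        for k, v in self.efficiency.head_.state_dict().items():
            arrays[f"eff.head.{k}"] = v
        if self.proportion is not None:
            meta["proportion"] = {"params": self.proportion.get_params(),
                                  "history": getattr(self.proportion, "history_", [])}
            for k, v in self.proportion.encoder_.state_dict().items():
                arrays[f"prop.enc.{k}"] = v
            for k, v in self.proportion.head_.state_dict().items():
                arrays[f"prop.head.{k}"] = v
        arrays["__meta__"] = np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8
        )
        with open(path, "wb") as fh:
            np.savez(fh, **arrays)

    @classmethod
    def load(cls, path) -> "BedictModel":
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            eff = EfficiencyModel(**meta["efficiency"]["params"])
            eff._build(np.random.default_rng(eff.seed))
            eff.encoder_.load_state_dict(
                {k[len("eff.enc."):]: z[k] for k in z.files if k.startswith("eff.enc.")}
            )
            eff.head_.load_state_dict(
                {k[len("eff.head."):]: z[k] for k in z.files if k.startswith("eff.head.")}
            )
            eff.history_ = meta["efficiency"]["history"]
            prop = None
            if "proportion" in meta:
                prop = ProportionModel(**meta["proportion"]["params"])
                prop._build(np.random.default_rng(prop.seed))
                prop.encoder_.load_state_dict(
                    {k[len("prop.enc."):]: z[k] for k in z.files
                     if k.startswith("prop.enc.")}
                )
                prop.head_.load_state_dict(
                    {k[len("prop.head."):]: z[k] for k in z.files
                     if k.startswith("prop.head.")}
                )
                prop.history_ = meta["proportion"]["history"]
        return cls(eff, prop, meta.get("metadata", {}))


# ---------------------------------------------------------------------------
# dataset-level operations

def gene_level_split(ds, fractions=(0.8, 0.1, 0.1), seed: int = 0):
    """Partition by gene into (train, test, validation); no gene spans two parts.

    Accepts a ScreenDataset (returns dataset subsets) or a site list (returns
    site-list subsets).  Gene counts match the requested fractions to the
    nearest integer; the remainder goes to the training partition.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions sum to {sum(fractions)}, not 1")
    sites = ds.sites if isinstance(ds, ScreenDataset) else list(ds)
    genes = sorted({s.gene_id for s in sites})
    rng = np.random.default_rng(seed)
    rng.shuffle(genes)
    g = len(genes)
    n_test = round(fractions[1] * g)
    n_val = round(fractions[2] * g)
    test_g = set(genes[:n_test])
    val_g = set(genes[n_test:n_test + n_val])
    train_g = set(genes[n_test + n_val:])

    def pick(gene_set):
        ids = [s.site_id for s in sites if s.gene_id in gene_set]
        if isinstance(ds, ScreenDataset):
            return ds.subset(ids)
        keep = set(ids)
        return [s for s in sites if s.site_id in keep]

    return pick(train_g), pick(test_g), pick(val_g)


def observed_efficiencies(ds: ScreenDataset) -> pd.DataFrame:
    """Per-site pooled efficiency, read depth and conditional outcome targets."""
    rows = []
    for s in ds.sites:
        dist = ds.distribution(s.site_id)
        if dist is None:
            continue
        n = sum(ds.assigned_reads(s.site_id, r) for r in ds.counts.get(s.site_id, {}))
        eff = 1.0 - dist.probs[dist.unedited_index]
        cond = {}
        if eff > 0:
            cond = {o: float(p / eff) for o, p in zip(dist.outcomes, dist.probs)
                    if o.is_edited and p > 0}
        rows.append({"site_id": s.site_id, "site": s, "eff": float(eff),
                     "n_reads": n, "edited_reads": float(eff) * n, "cond": cond})
    return pd.DataFrame(rows)


@dataclass
class TrainConfig:
    input_mode: str = "proto+pam"
    seed: int = 0
    max_epochs: int = 30
    proportion_max_epochs: int = 10
    fit_proportion: bool = True
    d_model: int = 64
    n_heads: int = 4
    n_layers: int = 2


def train(ds: ScreenDataset, config: TrainConfig | None = None,
          split=None) -> BedictModel:
    """Train the two-component model on a screen dataset.

    ``split`` is an optional precomputed (train, test, validation) dataset
    triple; by default a gene-level 80/10/10 split seeded from the config is
    used.  Sites with zero edited reads are excluded from the proportion loss.
    """
    cfg = config or TrainConfig()
    if split is None:
        split = gene_level_split(ds, seed=cfg.seed)
    train_ds, _, val_ds = split
    obs_tr = observed_efficiencies(train_ds)
    obs_va = observed_efficiencies(val_ds)
    if obs_tr.empty or obs_va.empty:
        raise ValueError("empty training or validation partition")

    eff = EfficiencyModel(input_mode=cfg.input_mode, seed=cfg.seed,
                          max_epochs=cfg.max_epochs, d_model=cfg.d_model,
                          n_heads=cfg.n_heads, n_layers=cfg.n_layers)
    eff.fit(list(obs_tr["site"]), obs_tr["eff"].to_numpy(),
            sample_weight=obs_tr["n_reads"].to_numpy(),
            validation_data=(list(obs_va["site"]), obs_va["eff"].to_numpy()))

    prop = None
    if cfg.fit_proportion:
        prop = ProportionModel(input_mode=cfg.input_mode, seed=cfg.seed,
                               max_epochs=cfg.proportion_max_epochs,
                               d_model=cfg.d_model, n_heads=cfg.n_heads,
                               n_layers=cfg.n_layers)
        prop.fit(list(obs_tr["site"]), list(obs_tr["cond"]),
                 sample_weight=obs_tr["edited_reads"].to_numpy())
    return BedictModel(eff, prop, metadata={
        "input_mode": cfg.input_mode, "seed": cfg.seed,
        "dataset": ds.metadata.get("editor", "unknown"),
    })


def evaluate(model: BedictModel | EfficiencyModel, ds: ScreenDataset,
             per_base_max_sites: int = 100, seed: int = 0) -> dict:
    """Correlations between predicted and observed efficiencies.

    Per-site totals use every site; pooled per-base correlations use the full
    outcome distribution and are computed on a seeded subsample of at most
    ``per_base_max_sites`` sites (full enumeration per site is quadratic in
    practice).  A tidy scatter frame is included for plotting.
    """
    obs = observed_efficiencies(ds)
    if len(obs) < 3:
        raise ValueError("need ≥3 sites to evaluate")
    sites = list(obs["site"])
    eff_model = model.efficiency if isinstance(model, BedictModel) else model
    pred = eff_model.predict(sites)
    meas = obs["eff"].to_numpy()
    out = {
        "spearman_total": _spearman(pred, meas),
        "pearson_total": float(stats.pearsonr(pred, meas).statistic),
        "scatter": pd.DataFrame({"site_id": obs["site_id"], "measured": meas,
                                 "predicted": pred}),
    }
    if isinstance(model, BedictModel) and model.proportion is not None:
        rng = np.random.default_rng(seed)
        idx = (np.arange(len(sites)) if len(sites) <= per_base_max_sites
               else rng.choice(len(sites), per_base_max_sites, replace=False))
        pb_pred, pb_meas = [], []
        for i in idx:
            s = sites[i]
            dist = ds.distribution(s.site_id)
            mp = per_position_efficiency(dist)
            pp = model.predict_per_position(s)
            for p in s.a_positions:
                pb_pred.append(pp[p - 1])
                pb_meas.append(mp[p - 1])
        out["spearman_perbase"] = _spearman(pb_pred, pb_meas)
        out["pearson_perbase"] = float(stats.pearsonr(pb_pred, pb_meas).statistic)
    return out


def learning_curve(ds: ScreenDataset, bin_fractions=None, seed: int = 0,
                   config: TrainConfig | None = None) -> pd.DataFrame:
    """Validation Spearman of the efficiency model vs training-set size.

    Gene-level nested subsets (each smaller bin is contained in every larger
    one) of the training partition are trained separately and scored on the
    shared validation partition.
    """
    fracs = sorted(bin_fractions or [0.1, 0.25, 0.5, 0.75, 1.0])
    if any(f <= 0 or f > 1 for f in fracs):
        raise ValueError("bin fractions must lie in (0, 1]")
    cfg = config or TrainConfig(seed=seed)
    train_ds, _, val_ds = gene_level_split(ds, seed=seed)
    obs_va = observed_efficiencies(val_ds)
    genes = sorted({s.gene_id for s in train_ds.sites})
    rng = np.random.default_rng(seed)
    rng.shuffle(genes)
    rows = []
    for f in fracs:
        keep = set(genes[:max(1, round(f * len(genes)))])
        sub = train_ds.subset([s.site_id for s in train_ds.sites if s.gene_id in keep])
        obs_tr = observed_efficiencies(sub)
        m = EfficiencyModel(input_mode=cfg.input_mode, seed=cfg.seed,
                            max_epochs=cfg.max_epochs, d_model=cfg.d_model,
                            n_heads=cfg.n_heads, n_layers=cfg.n_layers)
        m.fit(list(obs_tr["site"]), obs_tr["eff"].to_numpy(),
              sample_weight=obs_tr["n_reads"].to_numpy(),
              validation_data=(list(obs_va["site"]), obs_va["eff"].to_numpy()))
        pred = m.predict(list(obs_va["site"]))
        rows.append({"fraction": f, "n_sites": len(obs_tr),
                     "n_genes": len(keep),
                     "val_spearman": _spearman(pred, obs_va["eff"].to_numpy())})
    return pd.DataFrame(rows)


def input_ablation(ds: ScreenDataset, modes=INPUT_MODES, seed: int = 0,
                   max_epochs: int = 30) -> pd.DataFrame:
    """Validation Spearman of the efficiency model per input mode."""
    split = gene_level_split(ds, seed=seed)
    train_ds, _, val_ds = split
    obs_tr = observed_efficiencies(train_ds)
    obs_va = observed_efficiencies(val_ds)
    rows = []
    for mode in modes:
        m = EfficiencyModel(input_mode=mode, seed=seed, max_epochs=max_epochs)
        m.fit(list(obs_tr["site"]), obs_tr["eff"].to_numpy(),
              sample_weight=obs_tr["n_reads"].to_numpy(),
              validation_data=(list(obs_va["site"]), obs_va["eff"].to_numpy()))
        pred = m.predict(list(obs_va["site"]))
        rows.append({"input_mode": mode,
                     "val_spearman": _spearman(pred, obs_va["eff"].to_numpy())})
    return pd.DataFrame(rows)


# thin functional wrappers over the estimator surface -----------------------

def predict_efficiency(model: BedictModel, site: TargetSite) -> float:
    return model.predict_efficiency(site)


def predict_proportions(model: BedictModel, site: TargetSite) -> dict[Outcome, float]:
    return model.predict_proportions(site)


def predict_distribution(model: BedictModel, site: TargetSite) -> OutcomeDistribution:
    return model.predict_distribution(site)
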