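"""Assembly of the benchmarked risk architectures.

Thirteen neural architectures plus a logistic-regression baseline share one
high-level structure: (1) timestamped codes are mapped to time-aware
embeddings, (2) each of the two streams (diagnoses/procedures; medications/
vital signs) is integrated to a single scalar score by recurrent layers
and/or dot-product attention, and (3) the two scores are concatenated with
the static covariates and passed through a fully connected layer with a
sigmoid activation — the "logistic regression layer" whose output is the
30-day readmission risk.

The architectures factor along three orthogonal axes:

========================  =============  ==================  ===========
name                      embedding      sequence layer      pooling
========================  =============  ==================  ===========
ODE+RNN+Attention         neural ODE     bi-GRU              attention
ODE+RNN                   neural ODE     bi-GRU              final state
RNN(ODE time decay)+Att.  plain          bi-GRU, ODE decay   attention
RNN(ODE time decay)       plain          bi-GRU, ODE decay   final state
RNN(exp time decay)+Att.  plain          bi-GRU, exp decay   attention
RNN(exp time decay)       plain          bi-GRU, exp decay   final state
RNN(concat dt)+Attention  plain          bi-GRU, gap input   attention
RNN(concat dt)            plain          bi-GRU, gap input   final state
ODE+Attention             neural ODE     —                   attention
Attention(concat time)    time appended  —                   attention
MCE+RNN+Attention         MCE (frozen)   bi-GRU              attention
MCE+RNN                   MCE (frozen)   bi-GRU              final state
MCE+Attention             MCE (frozen)   —                   attention
LogisticBaseline          —              —                   —
========================  =============  ==================  ===========

The baseline uses the static covariates plus the most recent code of each
vital sign as covariates of a plain logistic regression.

A statsmodels-style facade (:class:`ReadmissionRiskModel` /
:class:`RiskModelResults`) wraps construction, fitting and evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat
from .data import Cohort, StayRecord, Vocabulary, pad_batch, DXPROC, MEDVIT
from .encoders import EmbeddingMatrix, embed, append_time, embedding_dim, \
    mce_train, ode_evolve_embedding
from .layers import AttentionPool, ScoreHead
from .nn import BiGRU, Linear, MLP, Module, dropout

__all__ = ["ArchSpec", "ARCHITECTURES", "build_model", "RiskNetwork",
           "ReadmissionRiskModel", "RiskModelResults", "code_score"]

# name -> (embedding mode, recurrent mode, pooling)
ARCHITECTURES: dict[str, tuple[str, str | None, str]] = {
    "ODE+RNN+Attention": ("ode", "plain", "attention"),
    "ODE+RNN": ("ode", "plain", "final"),
    "RNN(ODE time decay)+Attention": ("plain", "ode", "attention"),
    "RNN(ODE time decay)": ("plain", "ode", "final"),
    "RNN(exp time decay)+Attention": ("plain", "exp", "attention"),
    "RNN(exp time decay)": ("plain", "exp", "final"),
    "RNN(concat dt)+Attention": ("plain", "concat", "attention"),
    "RNN(concat dt)": ("plain", "concat", "final"),
    "ODE+Attention": ("ode", None, "attention"),
    "Attention(concat time)": ("concat_time", None, "attention"),
    "MCE+RNN+Attention": ("mce", "plain", "attention"),
    "MCE+RNN": ("mce", "plain", "final"),
    "MCE+Attention": ("mce", None, "attention"),
}
BASELINE = "LogisticBaseline"
ALL_ARCHITECTURES = list(ARCHITECTURES) + [BASELINE]


@dataclass
class ArchSpec:
    """Architecture identifier plus hyperparameters."""
    name: str = "ODE+RNN"
    ode_steps: int = 10
    dropout: float = 0.5
    scaled_attention: bool = True
    seed: int = 0
    embedding_dims: dict[str, int] | None = None  # default: size rule per stream
    # time units entering ODE blocks and decay/GRU gaps are divided by these
    # (days -> years for dx/proc, hours -> days for med/vit); a numerical
    # rescaling that keeps Euler steps well-conditioned over multi-year horizons
    time_scales: dict[str, float] | None = None
    mce_epochs: int = 6
    mce_finetune: bool = False  # MCE matrices frozen by default

    DEFAULT_TIME_SCALES = {DXPROC: 365.0, MEDVIT: 24.0}

    def __post_init__(self):
        if self.name not in ALL_ARCHITECTURES:
            raise ValueError(
                f"unknown architecture {self.name!r}; valid names: {ALL_ARCHITECTURES}")


class StreamEncoder(Module):
    """Embeds and integrates one code stream to a scalar score."""

    def __init__(self, v: int, spec: ArchSpec, rng: np.random.Generator,
                 stream: str, mce_matrix: EmbeddingMatrix | None = None):
        emb_mode, rnn_mode, pool = ARCHITECTURES[spec.name]
        d = (spec.embedding_dims or {}).get(stream, embedding_dim(v))
        self.emb_mode, self.rnn_mode, self.pool = emb_mode, rnn_mode, pool
        self.d = d
        self.ode_steps = spec.ode_steps
        if emb_mode == "mce":
            if mce_matrix is None:
                raise ValueError("MCE architectures need a pretrained embedding matrix")
            if mce_matrix.d != d:
                raise ValueError("MCE matrix width does not match the size rule")
            self.matrix = mce_matrix
            if not spec.mce_finetune:
                self.matrix.freeze()
        else:
            self.matrix = EmbeddingMatrix(v, d, rng=rng, stream=stream)
        self.dynamics = MLP(d, rng, out_zero_init=True) if emb_mode == "ode" else None
        self.time_scale = (spec.time_scales or ArchSpec.DEFAULT_TIME_SCALES).get(
            stream, 1.0)
        width = d + 1 if emb_mode == "concat_time" else d
        if rnn_mode is not None:
            self.rnn = BiGRU(width, width,
                             rng, time_mode=None if rnn_mode == "plain" else rnn_mode,
                             ode_steps=spec.ode_steps,
                             time_scale=self.time_scale)
            pooled_width = 2 * width
        else:
            self.rnn = None
            pooled_width = width
        self.attn = AttentionPool(pooled_width, rng, scaled=spec.scaled_attention) \
            if pool == "attention" else None
        self.head = ScoreHead(pooled_width, rng)
        self.dropout_p = spec.dropout

    def __call__(self, codes, elapsed, mask, rng: np.random.Generator,
                 training: bool = False) -> Tensor:
        if self.emb_mode == "ode":
            X = ode_evolve_embedding(codes, np.asarray(elapsed) / self.time_scale,
                                     mask, self.matrix,
                                     self.dynamics, self.ode_steps)
        else:
            X = embed(codes, mask, self.matrix)
            if self.emb_mode == "concat_time":
                X = append_time(X, elapsed, mask)
        X = dropout(X, self.dropout_p, rng, training)
        if self.rnn is not None:
            per_step, final = self.rnn(X, np.asarray(elapsed, dtype=float),
                                       np.asarray(mask, dtype=float))
            per_step = dropout(per_step, self.dropout_p, rng, training)
            H, pooled = per_step, final
        else:
            H, pooled = X, None
        if self.attn is not None:
            ctx, _ = self.attn(H, mask)
            ctx = dropout(ctx, self.dropout_p, rng, training)
        else:
            ctx = pooled
        return self.head(ctx)  # (B, 1)


def baseline_features(batch: dict[str, np.ndarray], vocab: Vocabulary) -> np.ndarray:
    """Static covariates plus a one-hot of each vital sign's most recent code."""
    static = batch["static"]
    codes, elapsed, mask = (batch[f"codes_{MEDVIT}"], batch[f"elapsed_{MEDVIT}"],
                            batch[f"mask_{MEDVIT}"])
    v = vocab.size(MEDVIT)
    onehot = np.zeros((static.shape[0], v))
    groups = vocab.vital_groups or {"all_vitals": list(range(v))}
    for i in range(static.shape[0]):
        valid = mask[i] > 0
        for members in groups.values():
            member_set = set(members)
            best_t, best_c = np.inf, None
            for c, t in zip(codes[i][valid], elapsed[i][valid]):
                if int(c) in member_set and t < best_t:
                    best_t, best_c = t, int(c)
            if best_c is not None:
                onehot[i, best_c] = 1.0
    return np.concatenate([static, onehot], axis=1)


class RiskNetwork(Module):
    """A fully assembled readmission-risk network (any of the 14 recipes)."""

    def __init__(self, spec: ArchSpec, vocabulary: Vocabulary, n_static: int,
                 mce_matrices: dict[str, EmbeddingMatrix] | None = None):
        self.spec = spec
        self.vocabulary = vocabulary
        rng = np.random.default_rng(spec.seed)
        self.is_baseline = spec.name == BASELINE
        if self.is_baseline:
            self.final = Linear(n_static + vocabulary.size(MEDVIT), 1, rng,
                                zero_init=True)
            self.streams = {}
        else:
            mce_matrices = mce_matrices or {}
            self.streams = {
                stream: StreamEncoder(vocabulary.size(stream), spec, rng, stream,
                                      mce_matrix=mce_matrices.get(stream))
                for stream in (DXPROC, MEDVIT)}
            self.stream_list = list(self.streams.values())  # for parameters()
            self.final = Linear(n_static + 2, 1, rng, zero_init=True)
            # the two stream scores enter the final layer with weight +1 at
            # initialisation: fixes the sign convention that a high code
            # score means high risk (the score scale is otherwise only
            # identified up to a sign flip absorbed by the head)
            self.final.W.data[n_static:, 0] = 1.0

    def logits(self, batch: dict[str, np.ndarray],
               rng: np.random.Generator | None = None,
               training: bool = False) -> Tensor:
        rng = np.random.default_rng(0) if rng is None else rng
        if self.is_baseline:
            x = Tensor(baseline_features(batch, self.vocabulary))
            return self.final(x)[:, 0]
        scores = [self.streams[stream](
            batch[f"codes_{stream}"], batch[f"elapsed_{stream}"],
            batch[f"mask_{stream}"], rng, training)
            for stream in (DXPROC, MEDVIT)]
        x = concat([Tensor(batch["static"])] + scores, axis=1)
        return self.final(x)[:, 0]

    def predict(self, stays: list[StayRecord], batch_size: int = 256) -> np.ndarray:
        """Deterministic evaluation-mode risks in (0, 1), batch order preserved.

        Risks are clipped away from exact 0/1 so the open-interval contract
        holds even for saturating logits (e.g. untrained networks fed raw
        elapsed times).
        """
        out = []
        for i in range(0, len(stays), batch_size):
            batch = pad_batch(stays[i:i + batch_size])
            out.append(self.logits(batch, training=False).sigmoid().data)
        risks = np.concatenate(out) if out else np.empty(0)
        return np.clip(risks, 1e-12, 1.0 - 1e-12)


def build_model(spec: ArchSpec, vocabulary: Vocabulary, n_static: int,
                mce_matrices: dict[str, EmbeddingMatrix] | None = None) -> RiskNetwork:
    """Construct the named architecture; raises for unrecognised names."""
    return RiskNetwork(spec, vocabulary, n_static, mce_matrices=mce_matrices)


def code_score(network: RiskNetwork, code: int, stream: str,
               elapsed: float = 0.0) -> float:
    """Score a single code: the stream score of a one-event stay.

    With a single unmasked element the attention weight is exactly one, so
    this equals passing the (time-augmented) embedding row through the score
    head — the per-code risk score used for interpretation.
    """
    enc = network.streams[stream]
    codes = np.array([[int(code)]])
    el = np.array([[float(elapsed)]])
    mask = np.ones((1, 1))
    return float(enc(codes, el, mask, np.random.default_rng(0), training=False).data[0, 0])


# -- statsmodels-style facade -------------------------------------------------

class ReadmissionRiskModel:
    """Readmission-risk model bound to a cohort.

    Parameters
    ----------
    cohort : Cohort
        Labelled stays with vocabulary and static covariate layout. Stays
        tagged ``train_valid`` are used for fitting; ``test`` for evaluation.
    arch : str or ArchSpec
        One of the 14 architecture names, or a full spec.
    """

    def __init__(self, cohort: Cohort, arch: str | ArchSpec = "ODE+RNN",
                 train_config=None):
        from .training import TrainConfig
        self.cohort = cohort
        self.spec = ArchSpec(name=arch) if isinstance(arch, str) else arch
        self.config = train_config or TrainConfig()
        self._mce: dict[str, EmbeddingMatrix] | None = None

    def _pretrain_mce(self, stays: list[StayRecord]) -> dict[str, EmbeddingMatrix]:
        """Unsupervised MCE pretraining on the training split only."""
        mats = {}
        for stream, codes_attr, el_attr in ((DXPROC, "codes_dxproc", "elapsed_dxproc"),
                                            (MEDVIT, "codes_medvit", "elapsed_medvit")):
            seqs = [(getattr(s, codes_attr), getattr(s, el_attr)) for s in stays]
            mats[stream] = mce_train(seqs, self.cohort.vocabulary.size(stream),
                                     epochs=self.spec.mce_epochs,
                                     seed=self.spec.seed + 7)
            mats[stream].stream = stream
        return mats

    def fit(self, config=None) -> "RiskModelResults":
        from .training import train
        config = config or self.config
        train_stays = [s for s in self.cohort.stays if s.split == "train_valid"]
        mce = None
        if ARCHITECTURES.get(self.spec.name, ("",))[0] == "mce":
            mce = self._mce or self._pretrain_mce(train_stays)
            self._mce = mce
        network = build_model(self.spec, self.cohort.vocabulary,
                              len(self.cohort.static_names), mce_matrices=mce)
        history = train(network, train_stays, config)
        return RiskModelResults(self, network, history)


@dataclass
class RiskModelResults:
    """Fitted network plus training history, evaluation and interpretation."""
    model: ReadmissionRiskModel
    network: RiskNetwork
    history: list[dict]

    def predict(self, stays: list[StayRecord] | None = None) -> np.ndarray:
        stays = stays if stays is not None else self.model.cohort.stays
        return self.network.predict(stays)

    def evaluate(self, stays: list[StayRecord] | None = None, n_boot: int = 100,
                 seed: int = 0):
        from .metrics import evaluate
        if stays is None:
            stays = [s for s in self.model.cohort.stays if s.split == "test"]
        scores = self.network.predict(stays)
        labels = np.array([s.label for s in stays])
        patients = np.array([s.patient_id for s in stays])
        return evaluate(labels, scores, patients, n_boot=n_boot, seed=seed)

    def code_scores(self, stream: str) -> np.ndarray:
        v = self.model.cohort.vocabulary.size(stream)
        return np.array([code_score(self.network, c, stream) for c in range(v)])

    def summary(self) -> str:
        spec = self.model.spec
        lines = [
            "Readmission risk model",
            "=" * 54,
            f"architecture:     {spec.name}",
            f"parameters:       {self.network.n_parameters()}",
            f"epochs trained:   {len(self.history)}",
        ]
        if self.history:
            lines.append(f"final train loss: {self.history[-1]['train_loss']:.4f}")
            if "valid_ap" in self.history[-1]:
                lines.append(
                    f"final valid AP:   {self.history[-1]['valid_ap']:.4f}")
        return "\n".join(lines)
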