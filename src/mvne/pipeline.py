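"""End-to-end orchestration: views -> P -> Y_init -> Y -> clusters -> metrics.

The :class:`MvNE` estimator is the primary surface.  ``fit`` takes a list of
view matrices (plus an optional presence mask for incomplete cohorts) and
runs the full method:

1. per-view preprocessing (variance ranking, z-scoring over present rows);
2. per-view neighbour distributions with entropy-calibrated bandwidths;
3. combination into a unified joint distribution (conflation by default;
   AvgProb / AvgData baselines selectable);
4. initial embedding from a stacked denoising autoencoder on the
   concatenated matrix (or PCA);
5. gradient-descent refinement of the embedding under KL(P||Q);
6. multi-objective simulated-annealing clustering of the embedding.

Per-stage seeds are derived from the master seed by fixed offsets so stages
can be re-run in isolation.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator

from . import metrics as _metrics
from .affinity import view_probabilities
from .amosa import AnnealSchedule, Archive, ClusterSolution, anneal, select_solution
from .conflation import (UnifiedProbability, average_data,
                         average_probabilities, conflate_views_complete,
                         conflate_views_incomplete)
from .data_model import (ConcatenatedMatrix, MultiViewDataset,
                         concatenate_views, normalize_features,
                         variance_rank_select)
from .embedding import EmbeddingState, OptimizerSettings, optimize
from .sae_init import SAEConfig, build_and_finetune, pca_embedding
from .synthgen import SynthSpec

__all__ = ["RunConfig", "RunResult", "MvNE", "run"]

# fixed per-stage seed offsets (kept below 2**31 after adding the master seed)
_SEED_OFFSETS = {"sae": 1, "embedding": 2, "amosa": 3, "synth": 4}


def _stage_seed(master: int, stage: str) -> int:
    return (int(master) + _SEED_OFFSETS[stage]) % (2 ** 31)


@dataclass
class RunConfig:
    """Everything a reproducible run needs; defaults follow the method's
    reference settings (k = 30 neighbours, 80-dimensional embedding, 2000
    gradient-descent iterations at base rate 200, momentum 0.5 -> 0.9)."""

    view_files: list[str] | None = None
    labels_file: str | None = None
    delimiter: str = "\t"
    synth: SynthSpec | None = None
    k: int = 30
    d_emb: int = 80
    k_features: int | None = None
    feature_fraction: float | None = None
    normalization: str = "zscore"
    combiner: str = "conflation"        # conflation | avgprob | avgdata
    init: str = "sae"                   # sae | pca
    iterations: int = 2000
    eta: float = 200.0
    momentum_init: float = 0.5
    momentum_final: float = 0.9
    momentum_switch: int = 250
    sae: SAEConfig | None = None
    schedule: AnnealSchedule | None = None
    selection: str = "best_pbm"
    seed: int = 0
    out_dir: str | None = None


@dataclass
class RunResult:
    P: UnifiedProbability
    Y_init: np.ndarray
    state: EmbeddingState
    archive: Archive
    solution: ClusterSolution
    summary: dict = field(default_factory=dict)


class MvNE(BaseEstimator):
    """Multi-view neighbourhood embedding with annealed clustering.

    Parameters
    ----------
    k : int, default 30
        Effective number of neighbours for the Gaussian bandwidth
        calibration (entropy target log k).
    d_emb : int, default 80
        Embedding dimensionality.
    combiner : {"conflation", "avgprob", "avgdata"}
        How per-view neighbour distributions are unified.
    init : {"sae", "pca"}
        Initial-embedding strategy.
    n_iter, eta, momentum_* :
        Gradient-descent settings for the KL minimization.
    preprocess : bool, default True
        Apply variance ranking (if ``k_features``/``feature_fraction`` set)
        and per-view z-scoring before the affinity step.  Disable when the
        inputs are already preprocessed.
    sae_* : autoencoder hyper-parameters (see :class:`SAEConfig`).
    anneal_* : annealing schedule (see :class:`AnnealSchedule`).
    selection : {"best_pbm", "supervised_nmi"}
        Solution choice from the Pareto archive; the supervised mode
        requires ``y`` at fit time and is a reporting convention, not an
        unsupervised result.
    random_state : int
        Master seed; per-stage seeds are derived from it.

    Attributes
    ----------
    P_ : UnifiedProbability
    Y_init_ : ndarray (n, d_emb)
    embedding_ : ndarray (n, d_emb)
    cost_trace_ : list of float
    archive_ : Archive
    solution_ : ClusterSolution
    labels_, n_clusters_ : selected crisp clustering.
    """

    def __init__(self, k: int = 30, d_emb: int = 80,
                 combiner: str = "conflation", init: str = "sae",
                 n_iter: int = 2000, eta: float = 200.0,
                 momentum_init: float = 0.5, momentum_final: float = 0.9,
                 momentum_switch: int = 250, preprocess: bool = True,
                 k_features: int | None = None,
                 feature_fraction: float | None = None,
                 normalization: str = "zscore",
                 sae_hidden: int = 500, sae_dropout: float = 0.05,
                 sae_pretrain_epochs: int = 200, sae_finetune_epochs: int = 400,
                 sae_batch_size: int = 64, sae_learning_rate: float = 1e-3,
                 anneal_t_max: float = 100.0, anneal_t_min: float = 0.001,
                 anneal_cooling: float = 0.9, anneal_iters: int = 100,
                 soft_limit: int = 50, hard_limit: int = 40,
                 selection: str = "best_pbm", random_state: int = 0):
        self.k = k
        self.d_emb = d_emb
        self.combiner = combiner
        self.init = init
        self.n_iter = n_iter
        self.eta = eta
        self.momentum_init = momentum_init
        self.momentum_final = momentum_final
        self.momentum_switch = momentum_switch
        self.preprocess = preprocess
        self.k_features = k_features
        self.feature_fraction = feature_fraction
        self.normalization = normalization
        self.sae_hidden = sae_hidden
        self.sae_dropout = sae_dropout
        self.sae_pretrain_epochs = sae_pretrain_epochs
        self.sae_finetune_epochs = sae_finetune_epochs
        self.sae_batch_size = sae_batch_size
        self.sae_learning_rate = sae_learning_rate
        self.anneal_t_max = anneal_t_max
        self.anneal_t_min = anneal_t_min
        self.anneal_cooling = anneal_cooling
        self.anneal_iters = anneal_iters
        self.soft_limit = soft_limit
        self.hard_limit = hard_limit
        self.selection = selection
        self.random_state = random_state

    # ------------------------------------------------------------- stages

    def _dataset(self, X, presence) -> MultiViewDataset:
        if isinstance(X, MultiViewDataset):
            return X
        views = [np.asarray(V, dtype=float) for V in X]
        n = views[0].shape[0]
        if presence is None:
            presence = np.ones((n, len(views)), dtype=bool)
        return MultiViewDataset(views=views,
                                sample_ids=[f"s{i}" for i in range(n)],
                                presence=presence)

    def _preprocess(self, ds: MultiViewDataset) -> MultiViewDataset:
        if not self.preprocess:
            return ds
        views = []
        for v, X in enumerate(ds.views):
            present = ds.presence[:, v]
            if self.k_features is not None or self.feature_fraction is not None:
                k = self.k_features
                if k is not None:
                    k = min(k, X.shape[1])
                X = variance_rank_select(X, k_features=k,
                                         fraction=self.feature_fraction,
                                         present=present)
            X = normalize_features(X, mode=self.normalization, present=present)
            views.append(X)
        return MultiViewDataset(views=views, sample_ids=list(ds.sample_ids),
                                presence=ds.presence, labels=ds.labels)

    def _unify(self, ds: MultiViewDataset) -> UnifiedProbability:
        if self.combiner == "avgdata":
            return average_data(ds.views, self.k, presence=ds.presence)
        vps = [view_probabilities(ds.views[v], self.k,
                                  present=ds.presence[:, v])
               for v in range(ds.n_views)]
        if self.combiner == "avgprob":
            return average_probabilities(vps, presence=ds.presence)
        if self.combiner == "conflation":
            if ds.is_complete:
                return conflate_views_complete(vps)
            return conflate_views_incomplete(vps, ds.presence)
        raise ValueError(f"unknown combiner {self.combiner!r}")

    def _initial_embedding(self, ds: MultiViewDataset) -> np.ndarray:
        concat: ConcatenatedMatrix = concatenate_views(ds)
        seed = _stage_seed(self.random_state, "sae")
        if self.init == "pca":
            return pca_embedding(concat.data, self.d_emb, seed=seed).Y_init
        if self.init != "sae":
            raise ValueError(f"unknown init {self.init!r}")
        cfg = SAEConfig(d_emb=self.d_emb, hidden_size=self.sae_hidden,
                        dropout_rate=self.sae_dropout,
                        pretrain_epochs=self.sae_pretrain_epochs,
                        finetune_epochs=self.sae_finetune_epochs,
                        batch_size=self.sae_batch_size,
                        learning_rate=self.sae_learning_rate, seed=seed)
        emb = build_and_finetune(concat.data, cfg)
        self.sae_loss_trace_ = emb.reconstruction_loss_trace
        return emb.Y_init

    # ---------------------------------------------------------------- fit

    def fit(self, X, y: np.ndarray | None = None,
            presence: np.ndarray | None = None) -> "MvNE":
        """Run the full method.

        ``X`` is a list of view matrices (n x d_v each) or a
        :class:`MultiViewDataset`; ``y`` (optional) enables the evaluation
        metrics and the supervised selection strategy.
        """
        ds = self._dataset(X, presence)
        if y is None and ds.labels is not None:
            y = ds.labels
        ds = self._preprocess(ds)
        self.P_ = self._unify(ds)
        self.Y_init_ = self._initial_embedding(ds)
        settings = OptimizerSettings(
            n_iter=self.n_iter, eta=self.eta,
            momentum_init=self.momentum_init,
            momentum_final=self.momentum_final,
            momentum_switch=self.momentum_switch,
            init_rescale=1e-2,
            seed=_stage_seed(self.random_state, "embedding"))
        self.state_ = optimize(self.P_, self.Y_init_, settings)
        self.embedding_ = self.state_.Y
        self.cost_trace_ = self.state_.cost_trace
        schedule = AnnealSchedule(
            t_max=self.anneal_t_max, t_min=self.anneal_t_min,
            cooling=self.anneal_cooling, iters_per_temp=self.anneal_iters,
            soft_limit=self.soft_limit, hard_limit=self.hard_limit,
            seed=_stage_seed(self.random_state, "amosa"))
        self.archive_ = anneal(self.embedding_, schedule)
        if self.selection == "supervised_nmi" and y is None:
            warnings.warn("supervised_nmi selection requires labels; "
                          "falling back to best_pbm")
        strategy = self.selection if (self.selection != "supervised_nmi"
                                      or y is not None) else "best_pbm"
        self.solution_ = select_solution(self.archive_, strategy, labels=y)
        self.labels_ = self.solution_.labels
        self.n_clusters_ = self.solution_.n_clusters
        return self

    def fit_predict(self, X, y=None, presence=None) -> np.ndarray:
        return self.fit(X, y=y, presence=presence).labels_

    def score_labels(self, y: np.ndarray) -> dict[str, float]:
        """External metrics of the selected solution against ground truth."""
        macro_f1, acc = _metrics.mapped_f1_accuracy(y, self.labels_)
        return {
            "nmi": _metrics.nmi(y, self.labels_),
            "ari": _metrics.ari(y, self.labels_),
            "macro_f1": macro_f1,
            "accuracy": acc,
        }


def _load_dataset(config: RunConfig) -> MultiViewDataset:
    from .data_model import align_views, read_labels, read_view
    from .synthgen import generate

    if config.synth is not None:
        spec = dataclasses.replace(
            config.synth, seed=_stage_seed(config.seed, "synth"))
        ds, _ = generate(spec)
        return ds
    if not config.view_files:
        raise ValueError("config needs view_files or a synth spec")
    raw = [read_view(p, delimiter=config.delimiter) for p in config.view_files]
    ds = align_views(raw)
    if config.labels_file:
        mapping = read_labels(config.labels_file, delimiter=config.delimiter)
        ds.labels = np.array([mapping.get(sid, -1) for sid in ds.sample_ids])
    return ds


def run(config: RunConfig) -> RunResult:
    """Execute a configured run and (optionally) write its artifacts."""
    ds = _load_dataset(config)
    sae = config.sae or SAEConfig(d_emb=config.d_emb)
    schedule = config.schedule or AnnealSchedule()
    est = MvNE(
        k=config.k, d_emb=config.d_emb, combiner=config.combiner,
        init=config.init, n_iter=config.iterations, eta=config.eta,
        momentum_init=config.momentum_init,
        momentum_final=config.momentum_final,
        momentum_switch=config.momentum_switch,
        k_features=config.k_features,
        feature_fraction=config.feature_fraction,
        normalization=config.normalization,
        sae_hidden=sae.hidden_size, sae_dropout=sae.dropout_rate,
        sae_pretrain_epochs=sae.pretrain_epochs,
        sae_finetune_epochs=sae.finetune_epochs,
        sae_batch_size=sae.batch_size, sae_learning_rate=sae.learning_rate,
        anneal_t_max=schedule.t_max, anneal_t_min=schedule.t_min,
        anneal_cooling=schedule.cooling, anneal_iters=schedule.iters_per_temp,
        soft_limit=schedule.soft_limit, hard_limit=schedule.hard_limit,
        selection=config.selection, random_state=config.seed)
    est.fit(ds)
    summary = {
        "combiner": config.combiner,
        "selection": est.selection,
        "uses_labels": config.selection == "supervised_nmi",
        "n_samples": ds.n_samples,
        "n_views": ds.n_views,
        "complete": bool(ds.is_complete),
        "K": int(est.n_clusters_),
        "XB": float(est.solution_.xb),
        "PBM": float(est.solution_.pbm),
        "final_cost": float(est.cost_trace_[-1]) if est.cost_trace_ else None,
        "seed": config.seed,
    }
    if ds.labels is not None:
        summary.update(est.score_labels(ds.labels))
    result = RunResult(P=est.P_, Y_init=est.Y_init_, state=est.state_,
                       archive=est.archive_, solution=est.solution_,
                       summary=summary)
    if config.out_dir:
        _write_artifacts(Path(config.out_dir), ds, result)
    return result


def _write_artifacts(out: Path, ds: MultiViewDataset, result: RunResult) -> None:
    import pandas as pd

    out.mkdir(parents=True, exist_ok=True)
    ids = ds.sample_ids
    pd.DataFrame(result.Y_init, index=ids).to_csv(out / "Y_init.tsv", sep="\t")
    pd.DataFrame(result.state.Y, index=ids).to_csv(out / "embedding.tsv", sep="\t")
    pd.DataFrame({"iteration": range(len(result.state.cost_trace)),
                  "cost": result.state.cost_trace}).to_csv(
        out / "cost_trace.tsv", sep="\t", index=False)
    rows = [{"K": s.n_clusters, "XB": s.xb, "PBM": s.pbm,
             "selected": s is result.solution}
            for s in result.archive.solutions]
    pd.DataFrame(rows).to_csv(out / "archive.tsv", sep="\t", index=False)
    pd.DataFrame({"sample": ids, "cluster": result.solution.labels}).to_csv(
        out / "labels.tsv", sep="\t", index=False)
    with open(out / "summary.json", "w") as fh:
        json.dump(result.summary, fh, indent=2)
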