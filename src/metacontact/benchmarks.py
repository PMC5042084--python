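"""Benchmark experiments on synthetic families.

Three canned experiments quantify the pipeline's behaviour under the study
conditions the package is validated at:

* :func:`covariation_auc_study` — contact-ranking AUC of each covariation
  method on families of L=30 with 2000 sampled sequences, averaged over
  seeds (parameter-recovery: can each engine separate true contact pairs
  from non-contacts?).
* :func:`meta_benchmark` — trains the two-stage meta-predictor on one set
  of families and compares its top-L/5 long-range precision against every
  individual covariation method on held-out families spanning a range of
  alignment depths.
* :func:`neff_stratified_benchmark` — mean top-L/5 long-range precision of
  a trained predictor across N_eff strata (families padded to controlled
  effective depths), the precision-versus-depth curve.

Benchmark families use L=36 and a few hundred sequences: long enough that
long-range (|i-j| > 23) pairs are plentiful, small enough that the full
covariation stack runs in seconds per family.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .covariation import coupling_scores
from .evaluation import ContactList, EvalConfig, contact_ranking_auc, topk_precision
from .pipeline import DEFAULT_METHODS, MetaPredictor, train_meta_predictor
from .simulator import SimConfig, generate_family
from .weighting import WeightedAlignment

BENCH_L = 36
BENCH_N = 400
#: (n_sequences, target_neff) of training families (None = no padding);
#: spans shallow to deep so the depth features are trained over the whole
#: range the benchmarks predict at
TRAIN_DEPTHS: Tuple[Tuple[int, Optional[int]], ...] = (
    (400, 10), (400, 25), (400, 60), (600, 150),
    (400, None), (600, 300), (600, None), (400, 80),
    (400, 15), (400, 40), (600, 200), (400, 120),
    (600, 400), (400, None), (600, None), (400, 30),
    (400, 10), (400, 12), (400, 20), (400, 25),
    (400, 8), (400, 50),
)


def _study_seed(seed: int, tag: int) -> int:
    return int(np.random.SeedSequence([seed, tag]).generate_state(1)[0] % 2**31)


def covariation_auc_study(
    seed: int,
    n_seeds: int = 10,
    L: int = 30,
    n_sequences: int = 2000,
    methods: Sequence[str] = DEFAULT_METHODS,
) -> pd.DataFrame:
    """Mean contact-ranking AUC per covariation method over seeded families."""
    rows = []
    for k in range(n_seeds):
        cfg = SimConfig(L=L, n_sequences=n_sequences, seed=_study_seed(seed, 100 + k))
        aln, topo = generate_family(cfg)
        wa = WeightedAlignment.from_alignment(aln)
        for m in methods:
            sm = coupling_scores(wa, m)
            rows.append({"seed": k, "method": sm.method,
                         "auc": contact_ranking_auc(sm, topo.contacts)})
    df = pd.DataFrame(rows)
    return (
        df.groupby("method")["auc"].agg(mean_auc="mean", n="count").reset_index()
    )


def _family_predictions(
    predictor: MetaPredictor, cfg: SimConfig
) -> Tuple[Dict[str, ContactList], set]:
    """Predictions of the meta-net and each individual method on one family."""
    aln, topo = generate_family(cfg)
    wa = WeightedAlignment.from_alignment(aln)
    scores = [coupling_scores(wa, m) for m in predictor.methods]
    preds = {sm.method: ContactList.from_score_matrix(sm) for sm in scores}
    cmap = predictor.predict(wa, scores=scores)
    preds["meta"] = ContactList.from_probability_map(cmap)
    truth1 = {(i + 1, j + 1) for i, j in topo.contacts}
    return preds, truth1


def train_benchmark_predictor(
    seed: int,
    depths: Sequence[Tuple[int, Optional[int]]] = TRAIN_DEPTHS,
    L: int = BENCH_L,
    methods: Sequence[str] = DEFAULT_METHODS,
) -> MetaPredictor:
    """Train a meta-predictor on families spanning a range of depths."""
    from .metanet import MetaNetConfig

    sims = [
        SimConfig(
            L=L,
            n_sequences=n_seq,
            target_neff=d,
            mutation_rate=0.05,
            seed=_study_seed(seed, 200 + k),
        )
        for k, (n_seq, d) in enumerate(depths)
    ]
    return train_meta_predictor(
        sims, net_config=MetaNetConfig(train_seed=_study_seed(seed, 299)), methods=methods
    )


def meta_benchmark(
    predictor: MetaPredictor,
    seed: int,
    n_families: int = 20,
    L: int = BENCH_L,
    n_sequences: int = BENCH_N,
    test_depths: Sequence[Optional[int]] = (10, 25, 60, 150, None),
    eval_config: Optional[EvalConfig] = None,
) -> pd.DataFrame:
    """Mean top-L/5 LR precision of the meta-predictor vs each single method.

    Held-out families cycle through ``test_depths`` so the comparison spans
    shallow to deep alignments.  Returns one row per predictor with columns
    (predictor, mean_precision, n_families).
    """
    eval_config = eval_config or EvalConfig()
    per_pred: Dict[str, List[float]] = {}
    for k in range(n_families):
        cfg = SimConfig(
            L=L,
            n_sequences=n_sequences,
            target_neff=test_depths[k % len(test_depths)],
            mutation_rate=0.05,
            seed=_study_seed(seed, 400 + k),
        )
        preds, truth1 = _family_predictions(predictor, cfg)
        for name, cl in preds.items():
            per_pred.setdefault(name, []).append(
                topk_precision(cl, truth1, eval_config, "LR")
            )
    rows = [
        {"predictor": name, "mean_precision": float(np.mean(v)), "n_families": len(v)}
        for name, v in per_pred.items()
    ]
    return pd.DataFrame(rows).sort_values("predictor", ignore_index=True)


def neff_stratified_benchmark(
    predictor: MetaPredictor,
    seed: int,
    strata: Sequence[int] = (10, 50, 200, 500),
    families_per_stratum: int = 4,
    L: int = BENCH_L,
    n_sequences: Optional[int] = None,
    eval_config: Optional[EvalConfig] = None,
) -> pd.DataFrame:
    """Mean meta-predictor top-L/5 LR precision per N_eff stratum.

    Paired design: the same base families (topology, Potts model and
    Gibbs samples, fixed by the per-family seed) appear in every stratum,
    padded to different effective depths.  A topology's long-range contact
    count caps its attainable precision, so unpaired strata would compare
    different ceilings; pairing isolates the depth effect.
    """
    eval_config = eval_config or EvalConfig()
    n_seq = n_sequences or max(BENCH_N, int(max(strata) * 1.2))
    rows = []
    for stratum in strata:
        for k in range(families_per_stratum):
            cfg = SimConfig(
                L=L,
                n_sequences=n_seq,
                target_neff=stratum,
                mutation_rate=0.05,
                seed=_study_seed(seed, 600 + k),
            )
            preds, truth1 = _family_predictions(predictor, cfg)
            rows.append(
                {
                    "neff_stratum": stratum,
                    "precision": topk_precision(preds["meta"], truth1, eval_config, "LR"),
                }
            )
    df = pd.DataFrame(rows)
    return (
        df.groupby("neff_stratum")["precision"]
        .agg(mean_precision="mean", n_families="count")
        .reset_index()
        .sort_values("neff_stratum", ignore_index=True)
    )
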