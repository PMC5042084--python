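"""End-to-end orchestration: training on synthetic families, full
prediction runs, run manifests, and aggregate benchmark statistics.

A trained predictor is a pair of stage models plus the feature
configuration they were fitted under; :func:`train_meta_predictor` builds
one entirely from simulated families, and :func:`run_predict` executes the
whole chain (parse -> weight -> covariation -> features -> stage 1 ->
stage 2 -> RR file) on an alignment file, emitting a JSON manifest beside
the output so every run is reproducible from its recorded inputs and seeds.

The module also ships the published CASP11 domain summary of the CONSIP2
server (per-domain length, top-L/5 long-range precision and N_eff) as a
packaged table, with :func:`table_stats` computing the aggregate statistics
(mean precision as a rounded percentage, integer-truncated median N_eff,
domain count).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .covariation import ScoreMatrix, coupling_scores
from .evaluation import ContactList, EvalConfig, topk_precision, write_rr
from .features import FeatureConfig, assemble_pair_features, depth_feature_vector
from .metanet import (
    ContactProbabilityMap,
    MetaNetConfig,
    MLPModel,
    predict_stage1,
    predict_stage2,
    train_stage1,
    train_stage2,
)
from .msa_io import Alignment, parse_msa
from .simulator import SimConfig, generate_family
from .weighting import WeightedAlignment

DEFAULT_METHODS = ("mi", "mip", "mfdca", "psicov", "plm")
_METHOD_TAGS = {"mi": "MI", "mip": "MIp", "mfdca": "mfDCA", "psicov": "PSICOV", "plm": "PLM"}


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

def _hash_obj(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


@dataclass
class RunManifest:
    command: str
    inputs: Dict[str, str] = field(default_factory=dict)
    config_hashes: Dict[str, str] = field(default_factory=dict)
    seeds: Dict[str, int] = field(default_factory=dict)
    version: str = __version__
    timestamp: str = ""
    stages: List[Dict[str, str]] = field(default_factory=list)

    def record_stage(self, name: str, status: str) -> None:
        self.stages.append({"stage": name, "status": status})

    def write(self, out_path) -> None:
        self.timestamp = time.strftime("%Y-%m-%dT%H:%M:%S")
        path = Path(str(out_path) + ".manifest.json")
        path.write_text(json.dumps(self.__dict__, indent=2, default=str))


# ---------------------------------------------------------------------------
# covariation feature stack
# ---------------------------------------------------------------------------

def compute_method_scores(
    walign: WeightedAlignment, methods: Sequence[str] = DEFAULT_METHODS
) -> List[ScoreMatrix]:
    """Run the configured covariation methods on one weighted alignment."""
    return [coupling_scores(walign, m) for m in methods]


def _labels_for_pairs(pairs, contacts0: Set[Tuple[int, int]]) -> np.ndarray:
    return np.array([1 if (i, j) in contacts0 else 0 for i, j in pairs])


# ---------------------------------------------------------------------------
# training on synthetic families
# ---------------------------------------------------------------------------

@dataclass
class MetaPredictor:
    """A trained two-stage predictor bundle."""

    stage1: MLPModel
    stage2: MLPModel
    feature_config: FeatureConfig
    net_config: MetaNetConfig
    methods: Tuple[str, ...] = DEFAULT_METHODS

    def save(self, path) -> None:
        path = Path(path)
        payload = {
            "format": "metacontact-meta-1",
            "methods": list(self.methods),
            "feature_config": self.feature_config.__dict__ | {
                "include_methods": list(self.feature_config.include_methods)
            },
            "net_config": self.net_config.__dict__,
            "stage1": self.stage1.to_dict(),
            "stage2": self.stage2.to_dict(),
        }
        path.write_text(json.dumps(payload))

    @classmethod
    def load(cls, path) -> "MetaPredictor":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "metacontact-meta-1":
            raise ValueError("not a metacontact meta-predictor file")
        fc = dict(payload["feature_config"])
        fc["include_methods"] = tuple(fc["include_methods"])
        return cls(
            stage1=MLPModel.from_dict(payload["stage1"]),
            stage2=MLPModel.from_dict(payload["stage2"]),
            feature_config=FeatureConfig(**fc),
            net_config=MetaNetConfig(**payload["net_config"]),
            methods=tuple(payload["methods"]),
        )

    def predict(
        self, walign: WeightedAlignment, scores: Optional[List[ScoreMatrix]] = None
    ) -> ContactProbabilityMap:
        scores = scores if scores is not None else compute_method_scores(walign, self.methods)
        feats = assemble_pair_features(walign, scores, config=self.feature_config)
        map1 = predict_stage1(self.stage1, feats)
        depth = depth_feature_vector(walign)
        return predict_stage2(self.stage2, map1, depth, self.net_config)


def train_meta_predictor(
    sim_configs: Sequence[SimConfig],
    feature_config: Optional[FeatureConfig] = None,
    net_config: Optional[MetaNetConfig] = None,
    methods: Sequence[str] = DEFAULT_METHODS,
) -> MetaPredictor:
    """Train both stages on simulated families with known contacts.

    Contact labels come from the generating topology (Cbeta-Cbeta <= 8 A in
    the coarse chain, matching the restraint threshold).  Stage 2 is trained
    on the stage-1 maps of the same families — its job is map-level cleanup,
    so it sees realistic stage-1 output rather than ground truth.
    """
    feature_config = feature_config or FeatureConfig(
        include_methods=tuple(_METHOD_TAGS[m] for m in methods)
    )
    net_config = net_config or MetaNetConfig()
    all_feats, all_labels = [], []
    per_family = []
    for cfg in sim_configs:
        alignment, topology = generate_family(cfg)
        walign = WeightedAlignment.from_alignment(alignment)
        scores = compute_method_scores(walign, methods)
        feats = assemble_pair_features(walign, scores, config=feature_config)
        labels = _labels_for_pairs(feats.pairs, topology.contacts)
        all_feats.append(feats.matrix)
        all_labels.append(labels)
        depth = depth_feature_vector(walign)
        per_family.append((feats, labels, depth))

    stacked = type(per_family[0][0])(
        pairs=[p for f, _, _ in per_family for p in f.pairs],
        matrix=np.vstack(all_feats),
        feature_names=per_family[0][0].feature_names,
        L=per_family[0][0].L,
    )
    stage1 = train_stage1(stacked, np.concatenate(all_labels), net_config)

    stage2_train = []
    for feats, labels, depth in per_family:
        map1 = predict_stage1(stage1, feats)
        stage2_train.append((map1, feats.pairs, depth, labels))
    stage2 = train_stage2(stage2_train, net_config)
    return MetaPredictor(
        stage1=stage1,
        stage2=stage2,
        feature_config=feature_config,
        net_config=net_config,
        methods=tuple(methods),
    )


# ---------------------------------------------------------------------------
# end-to-end prediction on files
# ---------------------------------------------------------------------------

def run_predict(msa_path, model_path, out_path, format: str = "fasta") -> RunManifest:
    """Full prediction chain from an alignment file to a CASP RR file."""
    manifest = RunManifest(command="predict", inputs={"msa": str(msa_path), "model": str(model_path)})
    stage = "load-model"
    try:
        predictor = MetaPredictor.load(model_path)
        manifest.record_stage(stage, "ok")
        stage = "parse"
        alignment = parse_msa(msa_path, format=format)
        manifest.record_stage(stage, "ok")
        stage = "weight"
        walign = WeightedAlignment.from_alignment(alignment)
        manifest.seeds["train_seed"] = predictor.net_config.train_seed
        manifest.config_hashes["feature_config"] = _hash_obj(predictor.feature_config.__dict__)
        manifest.record_stage(stage, "ok")
        stage = "predict"
        cmap = predictor.predict(walign)
        manifest.record_stage(stage, "ok")
        stage = "write-rr"
        write_rr(ContactList.from_probability_map(cmap), out_path)
        manifest.record_stage(stage, "ok")
    except Exception as e:
        manifest.record_stage(stage, f"error: {e}")
        manifest.write(out_path)
        raise
    manifest.write(out_path)
    return manifest


# ---------------------------------------------------------------------------
# aggregate statistics over a domain table
# ---------------------------------------------------------------------------

def load_casp11_table() -> pd.DataFrame:
    """The packaged CASP11 CONSIP2 per-domain results summary."""
    with resources.files("metacontact.data").joinpath(
        "casp11_consip2_results.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")


def table_stats(table: pd.DataFrame) -> Tuple[int, int, int]:
    """Aggregate a per-domain results table.

    Returns (mean precision rounded to the nearest integer percent,
    median N_eff truncated to an integer, domain count).
    """
    if len(table) == 0:
        raise ValueError("empty domain table")
    mean_precision = int(round(float(table["precision"].mean())))
    median_neff = int(float(table["neff"].median()))  # truncate fractional medians
    return mean_precision, median_neff, len(table)
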