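"""Config-driven pipeline: corpus -> train -> generate -> evaluate
(-> train predictor -> bias -> evaluate), with an experiment manifest.

The config is a plain mapping (YAML or JSON on disk).  It is validated
against a schema before any compute; every stage writes its outputs as
files under ``outdir`` and the manifest records the config snapshot,
seeds, corpus checksum, per-checkpoint metrics and artifact paths, so a
run can be repeated from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import chem
from .cells import ARCHITECTURES
from .experiments import fixture_memory_config
from .fixtures import FixtureSpec, gen_procedural_smiles
from .generator import GenerationPolicy, TrainConfig, train_generator
from .metrics import build_report, export_density, export_report
from .predictor import PredictorConfig, PropertyPredictor
from .rl import DIRECTIONS, LOSS_MODES, INVALID_POLICIES, RewardConfig, bias_generator
from .fixtures import toy_property_oracle

_SCHEMA = {
    "seed": int,
    "outdir": str,
    "corpus": dict,
    "generator": dict,
    "generation": dict,
    "evaluation": dict,
    "predictor": dict,
    "bias": dict,
}
_REQUIRED = ("outdir", "corpus", "generator")


class ConfigError(ValueError):
    """Invalid pipeline configuration; the message names the field."""


def load_config(path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith((".yml", ".yaml")):
        return yaml.safe_load(text)
    return json.loads(text)


def validate_config(cfg: dict) -> dict:
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    for key in cfg:
        if key not in _SCHEMA:
            raise ConfigError(f"unknown config section {key!r}")
    for key in _REQUIRED:
        if key not in cfg:
            raise ConfigError(f"missing required section {key!r}")
    gen = cfg["generator"]
    arch = gen.get("arch")
    if arch not in ARCHITECTURES:
        raise ConfigError(
            f"generator.arch: unknown architecture {arch!r}; "
            f"expected one of {ARCHITECTURES}")
    corpus = cfg["corpus"]
    if "path" not in corpus and "n" not in corpus:
        raise ConfigError("corpus: needs either 'path' or 'n'")
    if "bias" in cfg:
        b = cfg["bias"]
        if b.get("direction", "minimize") not in DIRECTIONS:
            raise ConfigError(f"bias.direction must be one of {DIRECTIONS}")
        if b.get("loss_mode", "reinforce") not in LOSS_MODES:
            raise ConfigError(f"bias.loss_mode must be one of {LOSS_MODES}")
        if b.get("invalid_policy", "score_anyway") not in INVALID_POLICIES:
            raise ConfigError(
                f"bias.invalid_policy must be one of {INVALID_POLICIES}")
    return cfg


def _checksum(strings) -> str:
    h = hashlib.sha256()
    for s in strings:
        h.update(s.encode())
        h.update(b"\n")
    return h.hexdigest()


def run_pipeline(config, outdir: Optional[str] = None) -> dict:
    """Execute the configured stages in order; returns the manifest.

    ``config`` is a mapping or a path to a YAML/JSON file.  Stage
    failures after validation are recorded in the manifest (with the
    stage name) and re-raised.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    cfg = validate_config(config)
    out = Path(outdir or cfg["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    manifest: dict = {"config": cfg, "seed": seed, "artifacts": {},
                      "stages": []}

    def _finish_stage(name):
        manifest["stages"].append(name)
        _write_manifest(manifest, out)

    try:
        # ---- corpus -------------------------------------------------
        ccfg = cfg["corpus"]
        if "path" in ccfg:
            corpus = [r.smiles for r in
                      chem.read_smiles_file(ccfg["path"], validate=True,
                                            max_mol_wt=ccfg.get("max_mol_wt"))]
        else:
            spec = FixtureSpec(kind="smiles", n=int(ccfg["n"]),
                               seed=int(ccfg.get("seed", seed)),
                               params=ccfg.get("params", {}))
            corpus = gen_procedural_smiles(spec)
        corpus_path = out / "corpus.smi"
        chem.write_smiles_file(corpus, corpus_path)
        manifest["corpus_checksum"] = _checksum(corpus)
        manifest["artifacts"]["corpus"] = str(corpus_path)
        _finish_stage("corpus")

        # ---- generator training ------------------------------------
        g = cfg["generator"]
        mem = fixture_memory_config(
            units=int(g.get("units", 32)),
            stack_width=int(g.get("stack_width", 16)),
            memory_rows=int(g.get("memory_rows", 50)),
            embedding=int(g.get("embedding", 32)))
        tcfg = TrainConfig(
            iterations=int(g.get("iterations", 2000)),
            batch_size=int(g.get("batch_size", 26)),
            eval_every=int(g.get("eval_every", 500)),
            eval_sample=int(g.get("eval_sample", 100)),
            learning_rate=float(g.get("learning_rate", 3e-3)),
            seed=seed)
        generator, log = train_generator(corpus, g["arch"], tcfg, mem)
        ckpt = out / "generator.ckpt"
        generator.save(ckpt)
        curve = [{"iteration": e["iteration"], "valid_pct": e["valid_pct"]}
                 for e in log if "valid_pct" in e]
        pd.DataFrame(curve).to_csv(out / "checkpoints.csv", index=False)
        manifest["checkpoint_table"] = curve
        manifest["artifacts"]["generator"] = str(ckpt)
        manifest["artifacts"]["checkpoints"] = str(out / "checkpoints.csv")
        _finish_stage("train_generator")

        # ---- generation --------------------------------------------
        gc = cfg.get("generation", {})
        policy = GenerationPolicy(
            epsilon=float(gc.get("epsilon", 0.05)),
            n_samples=int(gc.get("n_samples", 5)),
            max_length=int(gc.get("max_length", 60)))
        count = int(gc.get("count", 500))
        sample = generator.generate(count, policy, seed=seed + 1)
        gen_path = out / "generated.smi"
        chem.write_smiles_file(sample, gen_path)
        manifest["artifacts"]["generated"] = str(gen_path)
        _finish_stage("generate")

        # ---- evaluation --------------------------------------------
        ec = cfg.get("evaluation", {})
        prop = ec.get("property", "logP")
        report = build_report(sample, corpus, prop)
        export_report(report, out / "report.json")
        if report.property_values:
            export_density(report.property_values, out / "density.csv")
            manifest["artifacts"]["density"] = str(out / "density.csv")
        manifest["artifacts"]["report"] = str(out / "report.json")
        manifest["report"] = report.to_dict(include_values=False)
        _finish_stage("evaluate")

        # ---- predictor (optional) ----------------------------------
        scorer = None
        if "predictor" in cfg:
            pc = cfg["predictor"]
            pprop = pc.get("property", prop)
            n_train = min(int(pc.get("n_train", 2000)), len(corpus))
            rng = np.random.default_rng(seed)
            train_smiles = [corpus[i] for i in
                            rng.choice(len(corpus), n_train, replace=False)]
            targets = [chem.compute_property(s, pprop) for s in train_smiles]
            pcfg = PredictorConfig(seed=seed,
                                   epochs=int(pc.get("epochs", 8)),
                                   learning_rate=float(pc.get("learning_rate", 1e-3)))
            model = PropertyPredictor(generator.vocab, pcfg)
            mse = model.fit(train_smiles, targets)
            model.save(out / "predictor.ckpt")
            manifest["predictor_test_mse"] = mse
            manifest["artifacts"]["predictor"] = str(out / "predictor.ckpt")
            scorer = model.as_scorer()
            _finish_stage("train_predictor")

        # ---- biasing (optional) ------------------------------------
        if "bias" in cfg:
            b = cfg["bias"]
            direction = b.get("direction", "minimize")
            if scorer is None or b.get("reward") == "oracle":
                scorer = lambda s: toy_property_oracle(
                    s, b.get("oracle_mode", "heavy_atoms"))
            mag = abs(float(b.get("s", 0.25)))
            rcfg = RewardConfig.for_direction(
                direction, mag,
                loss_mode=b.get("loss_mode", "reinforce"),
                batch_size=int(b.get("batch_size", 24)),
                learning_rate=float(b.get("learning_rate", 3e-4)),
                invalid_policy=b.get("invalid_policy", "penalty"),
                penalty_value=float(b.get("penalty_value",
                                          30.0 if direction == "minimize" else 0.0)),
                seed=seed + 2)
            history = bias_generator(generator, scorer, rcfg,
                                     int(b.get("steps", 100)), policy)
            generator.save(out / "biased.ckpt")
            biased_sample = generator.generate(count, policy, seed=seed + 3)
            chem.write_smiles_file(biased_sample, out / "biased.smi")
            biased_report = build_report(biased_sample, corpus, prop)
            export_report(biased_report, out / "biased_report.json")
            manifest["bias_history_tail"] = history[-5:]
            manifest["biased_report"] = biased_report.to_dict(include_values=False)
            manifest["artifacts"].update({
                "biased_generator": str(out / "biased.ckpt"),
                "biased_generated": str(out / "biased.smi"),
                "biased_report": str(out / "biased_report.json")})
            _finish_stage("bias")
    except Exception as exc:  # record the failure, then propagate
        manifest["failure"] = {"stage": "incomplete", "error": repr(exc)}
        _write_manifest(manifest, out)
        raise
    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict, out: Path) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
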