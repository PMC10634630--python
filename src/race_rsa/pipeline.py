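"""End-to-end orchestration of the synthetic pipeline.

A run configuration is a plain dict (JSON on disk) with one section per
stage; unknown keys are rejected and every stochastic stage must carry an
explicit seed.  ``run_pipeline`` executes the stages in dependency order and
writes tidy CSV result tables, NIfTI volumes and a manifest (config hash,
seeds, package version) from which any result table can be regenerated.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .behaviour import behaviour_similarity, layer_behaviour_correlation
from .decoding import identity_decoding_fwer, race_decoding_fwer, within_between_difference
from .errors import ConfigError
from .io import (
    save_feature_sets,
    save_labels,
    save_pair_table,
    save_similarity_matrix,
    save_voxel_patterns,
)
from .mvpa import (
    adaptation_index,
    category_contrast,
    lopo_similarity,
    normalize_patterns,
    own_race_bias_contrast,
    race_similarity_contrast,
)
from .roi import ROIConfig, find_peak, flood_fill_roi, peak_report
from .rsm import build_similarity_matrix, pair_similarity
from .synthetic import (
    FeatureGenConfig,
    PatternGenConfig,
    gen_behaviour,
    gen_layer_features,
    gen_statmap,
    gen_voxel_patterns,
)

__all__ = ["run_pipeline", "demo_config", "MANIFEST_SCHEMA_VERSION"]

MANIFEST_SCHEMA_VERSION = "1.0"

_ALLOWED_SECTIONS = {"features", "decode", "behaviour", "patterns", "mvpa",
                     "adaptation", "statmap", "roi"}
_SEEDED_SECTIONS = {"features", "decode", "behaviour", "patterns", "statmap"}


def _validate(cfg: dict) -> None:
    unknown = set(cfg) - _ALLOWED_SECTIONS
    if unknown:
        raise ConfigError(f"unknown config sections: {sorted(unknown)}")
    for section in _SEEDED_SECTIONS & set(cfg):
        if "seed" not in cfg[section]:
            raise ConfigError(f"section {section!r} is stochastic and needs an explicit seed")
    if "decode" in cfg and "features" not in cfg:
        raise ConfigError("decode stage requires a features stage")
    if "behaviour" in cfg and "features" not in cfg:
        raise ConfigError("behaviour stage requires a features stage")
    if "roi" in cfg and "statmap" not in cfg:
        raise ConfigError("roi stage requires a statmap stage")
    for stage in ("mvpa", "adaptation"):
        if stage in cfg and "patterns" not in cfg:
            raise ConfigError(f"{stage} stage requires a patterns stage")


def demo_config(seed: int = 0) -> dict:
    """A small but complete synthetic end-to-end configuration."""
    return {
        "features": {"identities_per_race": 10, "feature_dims": 80,
                     "n_layers": 16, "seed": seed},
        "decode": {"n_perm": 199, "seed": seed + 1},
        "behaviour": {"layer_index": 14, "slope": 8.0, "guess_rate": 0.1,
                      "n_participants": 20, "seed": seed + 2},
        "patterns": {"n_participants": {"Asian": 12, "White": 12},
                     "n_voxels": 200, "seed": seed + 3},
        "mvpa": {},
        "adaptation": {},
        "statmap": {"shape": [30, 30, 30], "centres": [[15, 15, 15]],
                    "amplitudes": [6.0], "widths": [4.0], "seed": seed + 4},
        "roi": {"target_size": 500, "z_min": 2.3, "connectivity": 6},
    }


def run_pipeline(cfg: dict, out_dir) -> dict:
    """Execute the configured stages and write results under ``out_dir``."""
    _validate(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[str] = []

    def emit(df: pd.DataFrame, name: str) -> None:
        df.to_csv(out / name, index=False)
        outputs.append(name)

    feature_sets = pairs = sms = None
    if "features" in cfg:
        fcfg = FeatureGenConfig(**cfg["features"])
        feature_sets, pairs = gen_layer_features(fcfg)
        sms = [build_similarity_matrix(fs) for fs in feature_sets]
        save_feature_sets(feature_sets, out / "features.h5")
        save_labels(feature_sets[0], out / "labels.csv")
        save_pair_table(pairs, out / "pairs.csv")
        save_similarity_matrix(sms[-1], out / "rsm_final_layer.csv")
        outputs += ["features.h5", "labels.csv", "pairs.csv", "rsm_final_layer.csv"]

    if "decode" in cfg:
        dcfg = cfg["decode"]
        n_perm = int(dcfg.get("n_perm", 10_000))
        seed = int(dcfg["seed"])
        emit(race_decoding_fwer(sms, n_perm=n_perm, seed=seed), "race_decoding.csv")
        ident_rows = []
        layer_names = [sm.layer_name for sm in sms]
        for ri, race in enumerate(sorted(pairs["race"].unique())):
            sub = pairs[pairs["race"] == race].reset_index(drop=True)
            R = np.stack([pair_similarity(sm, sub) for sm in sms])
            tab = identity_decoding_fwer(
                R, sub["same_identity"].to_numpy(), layer_names,
                n_perm=n_perm, seed=seed + 100 + ri,
            )
            tab.insert(1, "race", race)
            ident_rows.append(tab)
        emit(pd.concat(ident_rows, ignore_index=True), "identity_decoding.csv")
        emit(within_between_difference(sms[-1]), "within_between_final_layer.csv")

    if "behaviour" in cfg:
        bcfg = dict(cfg["behaviour"])
        layer_index = int(bcfg.pop("layer_index", len(sms) - 2))
        gen_sm = sms[layer_index]
        rows = []
        for ri, race in enumerate(sorted(pairs["race"].unique())):
            sub = pairs[pairs["race"] == race].reset_index(drop=True)
            judgements = gen_behaviour(
                pair_similarity(gen_sm, sub), sub["trial_id"],
                slope=float(bcfg.get("slope", 8.0)),
                guess_rate=float(bcfg.get("guess_rate", 0.1)),
                n_participants=int(bcfg.get("n_participants", 70)),
                seed=int(bcfg["seed"]) + ri,
                group="all",
            )
            sub_prop = behaviour_similarity(judgements, sub)
            for sm in sms:
                res = layer_behaviour_correlation(sm, sub_prop, race=race)
                rows.append(dict(layer=res.layer_name, race=race, r=res.r,
                                 n_pairs=res.n_pairs, critical_r=res.critical_r,
                                 significant=res.significant))
        emit(pd.DataFrame(rows), "behaviour_rsa.csv")

    vps = None
    if "patterns" in cfg:
        pcfg = PatternGenConfig(**cfg["patterns"])
        vps = gen_voxel_patterns(pcfg)
        save_voxel_patterns(vps, out / "patterns.h5")
        outputs.append("patterns.h5")

    if "mvpa" in cfg:
        face_conds = [f"{r}/different" for r in ("Asian", "Black", "White")
                      if f"{r}/different" in vps.condition_labels]
        mvpa_conds = list(face_conds)
        if "Object/different" in vps.condition_labels:
            mvpa_conds.append("Object/different")
        norm = normalize_patterns(vps, mvpa_conds)
        ps = lopo_similarity(norm)
        emit(ps, "lopo_similarity.csv")
        emit(race_similarity_contrast(ps, face_conds), "race_similarity_contrast.csv")
        bias = own_race_bias_contrast(
            ps, face_conditions=("Asian/different", "White/different"),
            face_to_group={"Asian/different": "Asian", "White/different": "White"},
        )
        emit(bias.per_participant, "own_race_bias_cells.csv")
        emit(bias.group_tests.assign(interaction=bias.interaction),
             "own_race_bias_tests.csv")
        if "Object/different" in vps.condition_labels:
            emit(category_contrast(ps, face_conds, "Object/different"),
                 "category_contrast.csv")

    if "adaptation" in cfg:
        pairs_map = {
            r: (f"{r}/same", f"{r}/different")
            for r in ("Asian", "Black", "White", "Object")
            if f"{r}/same" in vps.condition_labels
        }
        emit(adaptation_index(vps, pairs_map), "adaptation.csv")

    if "statmap" in cfg:
        scfg = dict(cfg["statmap"])
        statmap = gen_statmap(
            shape=scfg.get("shape", (40, 48, 40)),
            centres=scfg.get("centres", ((20, 24, 20),)),
            amplitudes=scfg.get("amplitudes", (6.0,)),
            widths=scfg.get("widths", (3.0,)),
            noise_sd=float(scfg.get("noise_sd", 0.0)),
            seed=int(scfg["seed"]),
        )
        statmap.to_nifti(out / "zmap.nii.gz")
        outputs.append("zmap.nii.gz")

    if "roi" in cfg:
        rcfg = ROIConfig(
            target_size=int(cfg["roi"].get("target_size", 500)),
            z_min=float(cfg["roi"].get("z_min", 2.3)),
            fallback_rounding=int(cfg["roi"].get("fallback_rounding", 100)),
            connectivity=int(cfg["roi"].get("connectivity", 6)),
        )
        peak, _ = find_peak(statmap)
        roi = flood_fill_roi(statmap, peak, rcfg)
        roi.to_nifti(out / "roi.nii.gz")
        outputs.append("roi.nii.gz")
        emit(peak_report(statmap, {"roi": roi}), "roi_report.csv")

    manifest = {
        "schema_version": MANIFEST_SCHEMA_VERSION,
        "package_version": __version__,
        "config": cfg,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "outputs": outputs,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
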