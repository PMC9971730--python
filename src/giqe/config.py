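"""YAML (de)serialization of the run configuration.

One file holds every tunable: scene generator, feature constants and filter
banks, training grids, blur grid, and the global seed.  ``default_config``
emits the full default document so every knob is visible and diff-able.
"""

from __future__ import annotations

import yaml

from .features import FeatureConfig
from .loggabor import LogGaborBank
from .model import TrainConfig
from .pipeline import RunConfig
from .synthetic import SceneConfig

__all__ = ["config_to_dict", "config_from_dict", "default_config", "load_config", "save_config"]


def config_to_dict(cfg: RunConfig) -> dict:
    f, t, s = cfg.features, cfg.train, cfg.scene
    return {
        "seed": cfg.seed,
        "n_sources": cfg.n_sources,
        "lengths": list(cfg.lengths),
        "angles": [float(a) for a in cfg.angles],
        "scene": {
            "width": s.width,
            "height": s.height,
            "texture_scales": s.texture_scales,
            "vessel_density": s.vessel_density,
            "hue_base": list(s.hue_base),
            "seed": s.seed,
        },
        "features": {
            "a1": f.a1,
            "a2": f.a2,
            "a3": f.a3,
            "a_pc": f.a_pc,
            "alpha": f.alpha,
            "beta": f.beta,
            "pc_scales": f.pc_scales,
            "pc_orientations": f.pc_orientations,
            "mif_noise_var": f.mif_noise_var,
            "block_size": f.block_size,
            "lgf_bank": {
                "center_freqs": list(f.lgf_bank.center_freqs),
                "bandwidth_ratio": f.lgf_bank.bandwidth_ratio,
                "orientations": list(f.lgf_bank.orientations),
                "angular_spread": f.lgf_bank.angular_spread,
            },
        },
        "train": {
            "min_subset_size": t.min_subset_size,
            "svr_cost_grid": list(t.svr_cost_grid),
            "svr_epsilon_grid": list(t.svr_epsilon_grid),
            "rbf_gamma_grid": list(t.rbf_gamma_grid),
            "cv_folds": t.cv_folds,
            "split_fraction": t.split_fraction,
            "split_seed": t.split_seed,
        },
    }


def config_from_dict(doc: dict) -> RunConfig:
    base = config_to_dict(RunConfig())

    def merged(section: str) -> dict:
        out = dict(base[section])
        out.update(doc.get(section, {}) or {})
        return out

    s = merged("scene")
    fdoc = merged("features")
    bdoc = dict(base["features"]["lgf_bank"])
    bdoc.update((doc.get("features", {}) or {}).get("lgf_bank", {}) or {})
    t = merged("train")

    bank = LogGaborBank(
        center_freqs=tuple(bdoc["center_freqs"]),
        bandwidth_ratio=bdoc["bandwidth_ratio"],
        orientations=tuple(bdoc["orientations"]),
        angular_spread=bdoc["angular_spread"],
    )
    features = FeatureConfig(
        a1=fdoc["a1"], a2=fdoc["a2"], a3=fdoc["a3"], a_pc=fdoc["a_pc"],
        alpha=fdoc["alpha"], beta=fdoc["beta"],
        pc_scales=fdoc["pc_scales"], pc_orientations=fdoc["pc_orientations"],
        lgf_bank=bank, mif_noise_var=fdoc["mif_noise_var"],
        block_size=fdoc["block_size"],
    )
    return RunConfig(
        n_sources=doc.get("n_sources", base["n_sources"]),
        lengths=tuple(doc.get("lengths", base["lengths"])),
        angles=tuple(doc.get("angles", base["angles"])),
        scene=SceneConfig(
            width=s["width"], height=s["height"],
            texture_scales=s["texture_scales"],
            vessel_density=s["vessel_density"],
            hue_base=tuple(s["hue_base"]), seed=s["seed"],
        ),
        features=features,
        train=TrainConfig(
            min_subset_size=t["min_subset_size"],
            svr_cost_grid=tuple(t["svr_cost_grid"]),
            svr_epsilon_grid=tuple(t["svr_epsilon_grid"]),
            rbf_gamma_grid=tuple(t["rbf_gamma_grid"]),
            cv_folds=t["cv_folds"],
            split_fraction=t["split_fraction"],
            split_seed=t["split_seed"],
        ),
        seed=doc.get("seed", base["seed"]),
    )


def default_config() -> str:
    return yaml.safe_dump(config_to_dict(RunConfig()), sort_keys=False)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh) or {})


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        fh.write(yaml.safe_dump(config_to_dict(cfg), sort_keys=False))
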