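"""End-to-end orchestration: normalize -> trees -> CVA -> pFDA -> ACE -> size models.

Each stage writes one JSON report into the output directory and a combined
``summary.json`` ties them together; the validated configuration is echoed
verbatim into the summary for provenance.  All randomness flows from the
named seeds in the config, so a rerun with the same config is
byte-identical.  Stage failures abort downstream stages with a causal
message.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bodysize, comparative, discriminant, morphometrics, pfda, synthetic, treeops

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    outdir: str = "locomorph_run"
    seed: int = 0
    # either provide input paths ...
    measurements: str | None = None
    column_map: str | None = None
    trees: str | None = None
    occurrences: str | None = None
    ltrl: str | None = None
    # ... or simulate a bundle (dict of SimConfig overrides)
    simulate: dict | None = None
    targets: list[str] = field(default_factory=list)
    priors_mode: str = "proportional"
    lambda_grid: list[float] = field(default_factory=lambda: list(pfda.DEFAULT_GRID))
    ensemble_size: int = 100
    criterion: str = "aicc"
    date_method: str = "equal"
    root_length: float | None = None

    def validate(self) -> "RunConfig":
        if self.simulate is None and self.measurements is None:
            raise ValueError("config needs either input paths or a simulate block")
        if self.priors_mode not in ("proportional", "equal"):
            raise ValueError(f"bad priors_mode {self.priors_mode!r}")
        if self.criterion not in ("aicc", "aic"):
            raise ValueError(f"bad criterion {self.criterion!r}")
        if not all(0.0 <= g <= 1.0 for g in self.lambda_grid):
            raise ValueError("lambda grid must lie in [0, 1]")
        if self.ensemble_size < 1:
            raise ValueError("ensemble_size must be >= 1")
        return self

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw).validate()


def _dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, allow_nan=False) + "\n")


def _round(x, nd=10):
    return float(np.round(float(x), nd))


class StageError(RuntimeError):
    pass


def run_all(config: RunConfig) -> dict:
    """Run every stage; returns the combined summary (also written to disk)."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": dataclasses.asdict(config), "stages": {}}

    # ---- inputs -----------------------------------------------------------
    try:
        if config.simulate is not None:
            sim = synthetic.SimConfig(**{**config.simulate, "seed": config.seed})
            bundle = synthetic.simulate_dataset(sim)
            measurements = bundle.measurements.copy()
            trees = [bundle.tree] * config.ensemble_size
            trait = bundle.trait
            targets = list(config.targets)
            if targets:
                measurements.loc[
                    measurements.species.isin(targets), "locomotion"
                ] = morphometrics.UNKNOWN
        else:
            measurements = morphometrics.load_measurements(
                config.measurements, config.column_map
            )
            source = treeops.read_trees(config.trees)
            if config.date_method == "equal" and config.occurrences is not None:
                occ = treeops.load_occurrences(config.occurrences)
                rl = config.root_length
                if rl is None:
                    raise StageError("date_method 'equal' needs root_length")
                source = [treeops.date_equal(t, occ, rl) for t in source]
            trees = treeops.sample_tree_ensemble(
                source, min(config.ensemble_size, len(source)), config.seed
            )
            trait = None
            if config.ltrl is not None:
                ltrl = bodysize.taxon_ltrl_table(pd.read_csv(config.ltrl))
                trait = np.log10(ltrl)
            targets = list(config.targets)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"input stage failed: {exc}") from exc

    # ---- morphometrics ----------------------------------------------------
    try:
        shape = morphometrics.gm_normalize(measurements)
        means = morphometrics.species_means(shape)
        loggm = morphometrics.size_gm(measurements).groupby(
            measurements.species
        ).mean()
        unknown_mask = means.locomotion == morphometrics.UNKNOWN
        target_species = sorted(
            set(targets) | set(means.locomotion[unknown_mask].index)
        )
        train = morphometrics.SpeciesMeans(
            values=means.values.drop(index=target_species, errors="ignore"),
            n=means.n.drop(index=target_species, errors="ignore"),
            locomotion=means.locomotion.drop(index=target_species, errors="ignore"),
            columns=means.columns,
        )
        target_rows = means.values.loc[
            [s for s in target_species if s in means.values.index]
        ]
        means.to_csv(out / "species_means.csv", sidecar=str(out / "species_meta.json"))
        summary["stages"]["morphometrics"] = {
            "n_specimens": int(len(measurements)),
            "n_species": int(len(means.species)),
            "n_targets": len(target_rows),
            "log_gm": {sp: _round(v, 4) for sp, v in loggm.items()},
        }
    except Exception as exc:
        raise StageError(f"morphometrics stage failed: {exc}") from exc

    # ---- CVA --------------------------------------------------------------
    try:
        model = discriminant.fit_cva(train, config.priors_mode)
        jack = discriminant.jackknife_rates(train, config.priors_mode)
        mean_ratio, median_ratio = discriminant.posterior_to_prior_ratio(
            jack.per_class, model.priors
        )
        cva_report = {
            "variance_share_pct": [_round(v, 4) for v in model.variance_share],
            "cv1_cv2_variance_pct": _round(model.variance_share[:2].sum(), 4),
            "jackknife_overall": _round(jack.overall, 6),
            "jackknife_per_class": {
                c: (None if pd.isna(v) else _round(v, 6))
                for c, v in jack.per_class.items()
            },
            "posterior_to_prior_ratio": {
                "mean": _round(mean_ratio, 4),
                "median": _round(median_ratio, 4),
            },
            "targets": {
                t: {
                    "predicted": discriminant.classify(model, target_rows.loc[t]).predicted,
                    "posteriors": {
                        c: _round(v, 6)
                        for c, v in discriminant.classify(
                            model, target_rows.loc[t]
                        ).posteriors.items()
                    },
                }
                for t in target_rows.index
            },
        }
        _dump(cva_report, out / "cva.json")
        model.scores.to_csv(out / "cva_scores.csv", index_label="species")
        summary["stages"]["cva"] = cva_report
    except Exception as exc:
        raise StageError(f"cva stage failed: {exc}") from exc

    # ---- pFDA ensemble ----------------------------------------------------
    try:
        grid = np.asarray(config.lambda_grid, float)
        ens = pfda.ensemble_pfda(
            trees, train, target_rows, grid=grid, priors_mode=config.priors_mode
        )
        pfda_report = {
            "n_trees": len(trees),
            "lambdas": [_round(l, 4) for l in ens.lambdas],
            "jackknife_rates": [_round(r, 6) for r in ens.rates],
            "mean_jackknife_rate": _round(np.mean(ens.rates), 6),
            "mean_posteriors": {
                t: {c: _round(v, 6) for c, v in row.items()}
                for t, row in ens.mean_posteriors.iterrows()
            },
            "argmax_counts": {
                t: {c: int(v) for c, v in row.items()}
                for t, row in ens.argmax_counts.iterrows()
            },
            "failures": ens.failures,
        }
        _dump(pfda_report, out / "pfda.json")
        ens.posteriors.to_csv(out / "pfda_posteriors.csv")
        summary["stages"]["pfda"] = pfda_report
    except Exception as exc:
        raise StageError(f"pfda stage failed: {exc}") from exc

    # ---- ancestral states of locomotion -----------------------------------
    try:
        inferred = {
            t: max(
                pfda_report["mean_posteriors"][t],
                key=pfda_report["mean_posteriors"][t].get,
            )
            for t in target_rows.index
        }
        states = pd.concat([train.locomotion, pd.Series(inferred)]) if inferred else train.locomotion
        tree0 = trees[0]
        present = set(treeops.tip_labels(tree0))
        states = states[[s for s in states.index if s in present]]
        ace_tree = treeops.prune(tree0, list(states.index))
        mk = comparative.fit_mk(ace_tree, states)
        anc = comparative.marginal_states(ace_tree, states, mk)
        ace_report = {
            "q_per_myr": _round(mk.q, 8),
            "loglik": _round(mk.loglik, 6),
            "inferred_targets": inferred,
            "nodes": {
                node: {
                    "argmax": anc.argmax[node],
                    "probabilities": {
                        c: _round(v, 6) for c, v in anc.probabilities.loc[node].items()
                    },
                    "descendants": anc.descendants[node],
                }
                for node in anc.probabilities.index
            },
        }
        _dump(ace_report, out / "ace.json")
        summary["stages"]["ace"] = ace_report
    except Exception as exc:
        raise StageError(f"ace stage failed: {exc}") from exc

    # ---- body-size model selection ----------------------------------------
    if trait is not None:
        try:
            trait_tips = trait[[s for s in trait.index if s in present]]
            size_tree = treeops.prune(trees[0], list(trait_tips.index))
            fits = comparative.fit_all_models(
                size_tree, trait_tips, criterion=config.criterion
            )
            rec = comparative.ancestral_continuous(size_tree, trait_tips)
            size_report = {
                "criterion": config.criterion,
                "models": {
                    f.model: {
                        "loglik": _round(f.loglik, 6),
                        "aicc": _round(f.aicc, 6),
                        "weight": _round(f.weight, 6),
                        "params": {k: _round(v, 8) for k, v in f.params.items()},
                    }
                    for f in fits
                },
                "best_model": max(fits, key=lambda f: f.weight).model,
                "root_estimate": _round(rec.z0, 6),
            }
            _dump(size_report, out / "size_models.json")
            summary["stages"]["size"] = size_report
        except Exception as exc:
            raise StageError(f"size stage failed: {exc}") from exc

    _dump(summary, out / "summary.json")
    return summary
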