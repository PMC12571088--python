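"""End-to-end analysis pipeline.

Glue that runs the full chain on a loaded dataset: Procrustes
superimposition (with sliding semilandmarks), species-mean PCA, the four
threat-ordered extinction scenarios with Monte Carlo random-extinction
nulls, compositional diet analyses, and the permutation tests.  Returns a
plain nested dict so results serialize directly to JSON.
"""

from __future__ import annotations

import numpy as np

from .ecology import clr_transform, group_dispersion, ordinated_breadth, scenario_dispersion
from .extinction import (
    appd,
    apply_scenario,
    canonical_scenarios,
    procrustes_variance,
    random_extinction_null,
    targeted_vs_null,
)
from .inference import perm_anova, phylo_signal
from .io_formats import Dataset, THREATENED
from .morphospace import ordinate, species_mean_shapes
from .shape_core import superimpose


def run_pipeline(
    dataset: Dataset,
    seed: int = 0,
    slide: bool = True,
    n_reps: int = 100,
    n_perm: int = 999,
    subset: str = "both",
) -> dict:
    aligned = superimpose(dataset.configurations, slide=slide)
    species, means = species_mean_shapes(aligned, subset=subset)
    ordn = ordinate(means, ids=species)
    traits = dataset.traits.loc[species]
    statuses = traits["iucn"]

    results: dict = {
        "n_specimens": dataset.n_specimens,
        "n_species": len(species),
        "gpa": {
            "iterations": aligned.iterations_run,
            "converged": aligned.converged,
            "slid": aligned.slid,
        },
        "pct_variance": ordn.percent_variance[:5].round(4).tolist(),
        "threatened_pct": 100.0 * statuses.isin(THREATENED).mean(),
    }

    scenarios = canonical_scenarios(statuses)
    scen_out = []
    for sc in scenarios:
        res = apply_scenario(
            ordn.pc12, means, species, sc, depths=traits["max_depth_m"]
        )
        k = len(sc.removed)
        null = random_extinction_null(ordn.pc12, means, k, n_reps=n_reps, seed=seed)
        scen_out.append(
            {
                "name": sc.name,
                "n_removed": k,
                "pct_species_loss": 100.0 * k / len(species),
                "hull_area": res.hull.area,
                "pct_area_loss": res.pct_area_loss,
                "centroid_shift": res.shift.magnitude,
                "appd": res.appd,
                "depth_range": res.depth_range,
                "vs_null": {
                    "mean_pc1": targeted_vs_null(
                        float(np.mean(ordn.pc12[[species.index(s) for s in sc.survivors], 0])),
                        null["mean_pc1"], k=k,
                    ),
                    "mean_pc2": targeted_vs_null(
                        float(np.mean(ordn.pc12[[species.index(s) for s in sc.survivors], 1])),
                        null["mean_pc2"], k=k,
                    ),
                    "appd": targeted_vs_null(res.appd, null["appd"], k=k),
                },
            }
        )
    results["scenarios"] = scen_out
    results["baseline_appd"] = appd(means)
    results["procrustes_variance_by_iucn"] = {
        str(k): v for k, v in procrustes_variance(means, statuses.to_numpy()).items()
    }

    anova = perm_anova(means, statuses.to_numpy(), n_perm=n_perm, seed=seed)
    results["anova_iucn"] = {
        "r2": anova.r2, "f": anova.f, "z": anova.z, "p": anova.p,
    }

    if dataset.tree is not None and dataset.coverage["has_tree"].all():
        ps = phylo_signal(means, dataset.tree, species, n_perm=n_perm, seed=seed)
        results["phylo_signal"] = {"k": ps.k, "z": ps.z, "p": ps.p}

    if dataset.diets is not None:
        diet_sp = [s for s in species if s in dataset.diets.index]
        diets = dataset.diets.loc[diet_sp]
        clr = clr_transform(diets)
        disp = group_dispersion(clr, statuses.loc[diet_sp].to_numpy(),
                                n_perm=n_perm, seed=seed)
        breadth = ordinated_breadth(diets > 0)
        diet_scen = canonical_scenarios(statuses.loc[diet_sp])
        results["ecology"] = {
            "dispersion_f": disp.f,
            "dispersion_p": disp.p,
            "mean_dispersion": disp.overall_mean,
            "odb_thresholds": breadth.thresholds,
            "odb": breadth.odb.round(6).to_dict(),
            "scenario_dispersion": scenario_dispersion(clr, diet_scen).to_dict("records"),
        }
    return results
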