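"""End-to-end composition of the analysis stages.

survey_io -> coda -> ordination -> inference -> contamination index, with
every intermediate written to a run directory and a machine-readable
manifest recording the configuration.
"""
from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .survey_io import (ConcentrationTable, ElementPanel, read_concentrations,
                        harmonize_units, aggregate_replicates,
                        group_geometric_means, write_concentrations)
from .coda import clr_matrix, ilr_matrix
from .ordination import (compositional_pca, variance_explained,
                         biplot_coordinates, ratio_loadings,
                         plot_biplot, plot_ratio_loadings)
from .inference import manova_wilks, pairwise_hotelling
from .contamination import orient_pc, index_table, export_map_layer


@dataclass
class RunConfig:
    input_path: str | None = None          # None = bundled survey
    replicate_mode: str = "keep_all"
    lod_fraction: float = 0.65
    biplot_alpha: float = 0.0
    n_components: int = 2
    correction: str = "holm"
    out_dir: str = "lichencoda_run"
    seed: int = 0
    make_plots: bool = False


def analyze(table: ConcentrationTable, replicate_mode: str = "keep_all",
            correction: str = "holm") -> dict:
    """Run the statistical core in memory; returns a dict of results."""
    harm = harmonize_units(table)
    work = aggregate_replicates(harm, replicate_mode)
    C = clr_matrix(work.values)
    Z = ilr_matrix(work.values)
    pca = compositional_pca(C)
    pca = orient_pc(pca, panel=work.panel)
    man = manova_wilks(Z.values, work.groups.values)
    pw = pairwise_hotelling(Z.values, work.groups.values, method=correction)
    idx = index_table(pca, work)
    return {
        "table": work, "clr": C, "ilr": Z, "pca": pca,
        "manova": man, "pairwise": pw, "index": idx,
        "var_explained": pca.var_explained,
        "cum2": variance_explained(pca, 2),
        "group_gm": group_geometric_means(work),
    }


def run_pipeline(config: RunConfig, table: ConcentrationTable | None = None) -> Path:
    """Execute all stages and write artifacts + manifest to the run directory."""
    if table is None:
        if config.input_path is None:
            from .datasets import lichen_survey, PANEL
            table = lichen_survey()
        else:
            p = Path(config.input_path)
            if not p.exists():
                raise FileNotFoundError(f"input not found: {p}")
            from .datasets import PANEL
            table = read_concentrations(p, PANEL)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    res = analyze(table, config.replicate_mode, config.correction)

    stages = {}
    write_concentrations(res["table"], out / "harmonized.csv")
    stages["harmonized"] = "harmonized.csv"
    res["clr"].to_csv(out / "clr.csv")
    stages["clr"] = "clr.csv"
    res["ilr"].to_csv(out / "ilr.csv")
    stages["ilr"] = "ilr.csv"
    pca = res["pca"]
    pca_report = {
        "var_explained": [float(v) for v in pca.var_explained],
        "cumulative_2pc": float(res["cum2"]),
        "singular_values": [float(s) for s in pca.singular_values],
        "loadings": res["pca"].loadings.iloc[:, :config.n_components]
                      .round(10).to_dict(),
    }
    (out / "pca.json").write_text(json.dumps(pca_report, indent=1))
    stages["pca"] = "pca.json"
    man = res["manova"]
    test_report = {
        "manova": {"wilks_lambda": man.wilks_lambda, "f": man.f_stat,
                   "df": list(man.df), "p": man.p_value,
                   "groups": list(man.groups),
                   "n_per_group": list(man.n_per_group), "dim": man.dim},
        "pairwise": res["pairwise"].to_dict(orient="records"),
    }
    (out / "tests.json").write_text(json.dumps(test_report, indent=1))
    stages["tests"] = "tests.json"
    res["index"].to_csv(out / "index.csv", index=False)
    stages["index"] = "index.csv"
    if res["table"].coords is not None:
        export_map_layer(res["index"], out / "index.geojson", "geojson")
        stages["map_layer"] = "index.geojson"
    else:
        export_map_layer(res["index"], out / "index_flat.csv", "csv")
        stages["map_layer"] = "index_flat.csv"
    if config.make_plots:
        plot_biplot(pca, groups=res["table"].groups.values,
                    alpha=config.biplot_alpha, path=out / "biplot.png")
        plot_ratio_loadings(pca, path=out / "ratio_loadings.png")
    manifest = {
        "config": asdict(config),
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "stages": stages,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out
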