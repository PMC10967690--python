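"""End-to-end orchestration: simulate -> sfi -> stats -> ecology -> network.

``run_all`` executes every stage on either simulated data, loaded files, or
the published-table fixtures, writes each stage's outputs under one report
directory, and returns a run manifest (seed, config digest, per-file
checksums). Stage failures abort with the stage name; partial outputs are
retained.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import ecology, fertility, network, simulate, stats
from .io import (MeasurementTable, OtuTable, PipelineConfig,
                 read_measurement_table, read_otu_table, write_manifest,
                 write_measurement_table)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunManifest:
    path: Path
    out_dir: Path
    files: list[Path]


def _default_soil_spec() -> simulate.SoilSimSpec:
    # baselines loosely follow the magnitudes of the published soil table
    variables = {
        "pH": (4.8, 0.08), "TN": (1.0, 0.05), "AN": (25.0, 1.5),
        "AMN": (12.0, 0.8), "NN": (12.0, 1.0), "TC": (10.0, 0.5),
        "SOM": (18.0, 1.0), "AP": (8.0, 0.8), "AK": (150.0, 8.0),
    }
    effects = {}
    for period in simulate.PERIODS:
        effects[("T1", period)] = {"TN": 0.15, "AN": 6.0, "AMN": 2.5,
                                   "NN": 4.0, "TC": 1.2, "SOM": 2.5,
                                   "AP": 3.0, "AK": 40.0}
        effects[("T2", period)] = {"TN": 0.25, "AN": 8.0, "AMN": 3.0,
                                   "NN": 5.0, "TC": 1.8, "SOM": 3.5,
                                   "AP": 2.0, "AK": 55.0}
    return simulate.SoilSimSpec(variables=variables, effects=effects)


def _default_otu_spec() -> simulate.OtuSimSpec:
    return simulate.OtuSimSpec(
        n_samples_per_group={"CK": 12, "T1": 12, "T2": 12},
        n_otus=60, sigma=1.0,
        blocks=[list(range(0, 10)), list(range(10, 20))], rho=0.8,
        group_effects={"T1": {i: 1.0 for i in range(20, 25)},
                       "T2": {i: -1.0 for i in range(25, 30)}},
        depth=20_000)


def run_all(config: PipelineConfig, out_dir: str | Path | None = None,
            soil_path: str | Path | None = None,
            otu_path: str | Path | None = None,
            do_simulate: bool = False,
            published_fixtures: bool = False) -> RunManifest:
    """Run every stage and write a report directory.

    Exactly one data source applies: ``do_simulate`` (generators with the
    run seed), ``published_fixtures`` (published-table pseudo-replicates; no
    OTU stages), or explicit file paths.
    """
    out = Path(out_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []

    # -- stage: data -------------------------------------------------------
    stage = "data"
    try:
        otu = None
        if published_fixtures:
            soil, tea = simulate.published_tables()
            write_measurement_table(tea, out / "tea_fixture.csv")
            files.append(out / "tea_fixture.csv")
        elif do_simulate:
            soil, _ = simulate.simulate_soil(_default_soil_spec(), config.seed)
            otu, _ = simulate.simulate_otu(_default_otu_spec(), config.seed)
        else:
            if soil_path is None:
                raise FileNotFoundError("no soil measurement file given")
            soil = read_measurement_table(soil_path)
            if otu_path is not None:
                otu = read_otu_table(otu_path)
        write_measurement_table(soil, out / "soil.csv")
        files.append(out / "soil.csv")
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError(stage, exc) from exc

    # -- stage: sfi --------------------------------------------------------
    stage = "sfi"
    try:
        result = fertility.compute_sfi(soil,
                                       reference=config.reference_treatment)
        result.sfi.rename_axis("sample_id").to_csv(out / "sfi_per_sample.csv")
        result.summary.to_csv(out / "sfi_summary.csv")
        (out / "sfi_weights.json").write_text(json.dumps(
            {"weights": result.weights.weights.round(12).to_dict(),
             "eigenvalues": list(result.weights.eigenvalues.round(12)),
             "retained_components": [int(i) for i in result.weights.retained]},
            indent=2, sort_keys=True))
        files += [out / "sfi_per_sample.csv", out / "sfi_summary.csv",
                  out / "sfi_weights.json"]
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # -- stage: stats ------------------------------------------------------
    stage = "stats"
    try:
        letters = stats.letter_table(soil, alpha=config.alpha)
        letters.to_csv(out / "duncan_letters.csv")
        pct = stats.percent_change(soil, config.reference_treatment)
        pct.to_csv(out / "percent_change.csv")
        files += [out / "duncan_letters.csv", out / "percent_change.csv"]
        if published_fixtures:
            tea_pct = stats.percent_change(tea, config.reference_treatment)
            tea_pct.to_csv(out / "tea_percent_change.csv")
            files.append(out / "tea_percent_change.csv")
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # -- stages requiring an OTU table ------------------------------------
    if otu is not None:
        stage = "ecology"
        try:
            dm = ecology.bray_curtis(otu)
            pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
                out / "bray_curtis.csv")
            ord_ = ecology.nmds(dm, seed=config.seed)
            pd.DataFrame(ord_.embedding_, index=dm.ids,
                         columns=["NMDS1", "NMDS2"]).to_csv(
                out / "nmds_coordinates.csv")
            groups = [s.split(".")[0] for s in dm.ids]
            ano = ecology.anosim(dm, groups,
                                 n_permutations=config.n_permutations,
                                 seed=config.seed)
            (out / "anosim.json").write_text(json.dumps(
                {"R": ano.r, "p_value": ano.p_value, "stress": ord_.stress_,
                 "n_permutations": ano.n_permutations, "seed": config.seed},
                indent=2))
            files += [out / "bray_curtis.csv", out / "nmds_coordinates.csv",
                      out / "anosim.json"]
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc

        stage = "network"
        try:
            edges = network.spearman_edges(
                otu, r_min=config.network_r_min, p_max=config.network_p_max,
                prevalence_min=config.prevalence_min)
            g = network.build_graph(edges, otu)
            if g.number_of_edges():
                topo = network.null_model_compare(g, seed=config.seed)
            else:
                topo = network.topology(g)
            files += network.write_network(g, topo, out)
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc

    manifest_path = write_manifest(out, config, files)
    return RunManifest(manifest_path, out, files)
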