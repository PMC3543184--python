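"""End-to-end translatome pipeline with reproducible TSV outputs.

Order of stages: empty-spot cutoff -> reference/RNA-quantity/inter-series
normalization -> per-gene proportions and occupancy -> bootstrap peak
fraction -> ribosome density -> theoretical-maximum density filter ->
covariance models. A gene-set ledger records how many genes survive each
stage. All tabular outputs carry a commented header with the config hash
and seed so reruns are byte-identical and auditable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import normalize as nz
from . import quantify as qt
from . import stats as st
from .normalize import ARRAY_LABELS, ArraySeries
from .profile import RibosomeCalibration

__all__ = ["PipelineConfig", "PipelineResult", "PipelineError",
           "run_pipeline", "load_array_series"]


class PipelineError(RuntimeError):
    """A stage failure; the message names the stage and the offender."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage: {stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs.

    ``features`` must be indexed by gene_id and include ``cds_length_nt``;
    the covariate columns of the default model spec and an optional
    ``protein_level`` column enable the modeling stage.
    """

    series: ArraySeries
    features: pd.DataFrame
    calibration: RibosomeCalibration
    n_boot: int = 10000
    conf: float = 0.95
    seed: int = 0
    fit_models: bool = True
    out_dir: Path | None = None

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "n_genes": self.series.n_genes,
                "n_replicates": self.series.n_replicates,
                "n_boot": self.n_boot,
                "conf": self.conf,
                "seed": self.seed,
                "a": self.calibration.a,
                "b": list(self.calibration.b),
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    ledger: dict[str, int]
    normalized: nz.NormalizedSeries
    translatome: pd.DataFrame
    modeling_set: pd.DataFrame
    occupancy_fit: st.ModelFit | None = None
    density_fit: st.ModelFit | None = None
    protein_fits: tuple[st.ModelFit, st.ModelFit] | None = None
    config_hash: str = ""
    seed: int = 0
    outputs: dict[str, Path] = field(default_factory=dict)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage and (optionally) write the output bundle."""
    series = config.series
    ledger = {"input": series.n_genes}

    try:
        normalized = nz.normalize_series(series)
    except ValueError as exc:
        stage = ("rna_quantity_correction" if "RNA" in str(exc)
                 else "normalization")
        raise PipelineError(stage, str(exc)) from exc
    ledger["cutoff"] = len(normalized.kept_genes)

    missing = [g for g in normalized.kept_genes if g not in config.features.index]
    if missing:
        raise PipelineError(
            "translatome", f"features table lacks genes: {missing[:5]} ..."
        )
    cds = config.features.loc[normalized.kept_genes, "cds_length_nt"].to_numpy(float)
    if not config.calibration.fraction_ranges:
        raise PipelineError("ribosome_density",
                            "calibration has no fraction_ranges for D-H")
    translatome = qt.compute_translatome(
        normalized.ncr_values,
        normalized.kept_genes,
        cds,
        config.calibration,
        n_boot=config.n_boot,
        conf=config.conf,
        seed=config.seed,
    )
    ledger["peak_assigned"] = int((~translatome["peak_unassigned"]).sum())

    modeling_set = qt.filter_max_density(translatome)
    ledger["density_filtered"] = len(modeling_set)

    occupancy_fit = density_fit = protein_fits = None
    if config.fit_models:
        feats = config.features.loc[modeling_set.index]
        try:
            spec = st.default_model_spec("ribosome_occupancy")
            occupancy_fit = st.fit_covariance_model(
                feats, modeling_set["occupancy"], spec
            )
            density_fit = st.fit_covariance_model(
                feats, modeling_set["density"],
                st.default_model_spec("ribosome_density"),
            )
            ledger["model_complete_cases"] = occupancy_fit.n_used
            if "protein_level" in feats.columns and \
                    feats["protein_level"].notna().sum() >= 20:
                pf = feats.assign(
                    occupancy=modeling_set["occupancy"],
                    density=modeling_set["density"],
                )
                protein_fits = st.protein_level_model(pf, pf["protein_level"])
        except ValueError as exc:
            raise PipelineError("covariance_model", str(exc)) from exc

    result = PipelineResult(
        ledger=ledger,
        normalized=normalized,
        translatome=translatome,
        modeling_set=modeling_set,
        occupancy_fit=occupancy_fit,
        density_fit=density_fit,
        protein_fits=protein_fits,
        config_hash=config.config_hash(),
        seed=config.seed,
    )
    if config.out_dir is not None:
        result.outputs = _write_outputs(config, result)
    return result


def load_array_series(intensities_tsv: str | Path,
                      fractions_tsv: str | Path) -> ArraySeries:
    """Read the long-format intensity and fraction-metadata TSVs."""
    inten = pd.read_csv(intensities_tsv, sep="\t", comment="#")
    meta = pd.read_csv(fractions_tsv, sep="\t", comment="#")
    genes = list(dict.fromkeys(inten["gene_id"]))
    reps = sorted(inten["replicate"].unique())
    gi = {g: i for i, g in enumerate(genes)}
    aj = {a: j for j, a in enumerate(ARRAY_LABELS)}
    tensor = np.full((len(genes), 8, len(reps)), np.nan)
    tensor[
        inten["gene_id"].map(gi),
        inten["array"].map(aj),
        inten["replicate"].astype(int),
    ] = inten["intensity"].to_numpy(float)
    if np.any(np.isnan(tensor)):
        raise PipelineError("ingest", "incomplete intensity tensor")
    if not {"rna_quantity_ug", "empty_mean", "empty_sd"} <= set(meta.columns):
        raise PipelineError(
            "rna_quantity_correction",
            "fraction metadata lacks RNA quantities or empty-spot statistics",
        )
    rna = np.empty((8, len(reps)))
    empty = np.empty((8, 2))
    for arr, grp in meta.groupby("array"):
        rna[aj[arr]] = grp.sort_values("replicate")["rna_quantity_ug"].to_numpy()
        empty[aj[arr]] = grp[["empty_mean", "empty_sd"]].iloc[0].to_numpy()
    return ArraySeries(tensor, genes, empty, rna)


def _header(config: PipelineConfig, stage: str) -> str:
    return (f"# config_hash={config.config_hash()}\n"
            f"# seed={config.seed}\n# stage={stage}\n")


def _write_tsv(path: Path, df: pd.DataFrame, config: PipelineConfig,
               stage: str, index: bool) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config, stage))
        df.to_csv(fh, sep="\t", index=index)


def _write_outputs(config: PipelineConfig,
                   result: PipelineResult) -> dict[str, Path]:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["translatome"] = out / "translatome.tsv"
    _write_tsv(paths["translatome"], result.translatome, config,
               "translatome", index=True)

    qc_rows = [
        {"array": ARRAY_LABELS[j + 1], "replicate": k,
         "r_hat": result.normalized.fit_params[j, k, 0],
         "b_hat": result.normalized.fit_params[j, k, 1],
         "n_clipped": int(result.normalized.clipped[:, j, k].sum())}
        for j in range(7) for k in range(config.series.n_replicates)
    ]
    paths["qc"] = out / "qc.tsv"
    _write_tsv(paths["qc"], pd.DataFrame(qc_rows), config, "qc", index=False)

    ledger_df = pd.DataFrame(
        list(result.ledger.items()), columns=["stage", "n_genes"]
    )
    paths["ledger"] = out / "gene_set_ledger.tsv"
    _write_tsv(paths["ledger"], ledger_df, config, "ledger", index=False)

    if result.occupancy_fit is not None:
        rows = []
        for name, fit in (("ribosome_occupancy", result.occupancy_fit),
                          ("ribosome_density", result.density_fit)):
            for term in fit.selected:
                rows.append({"model": name, "term": term,
                             "coefficient": fit.coefficients[term],
                             "p_value": fit.p_values[term],
                             "adj_r2": fit.adj_r2, "n": fit.n_used})
        paths["models"] = out / "model_coefficients.tsv"
        _write_tsv(paths["models"], pd.DataFrame(rows), config,
                   "covariance_model", index=False)
    return paths
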