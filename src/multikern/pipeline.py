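"""End-to-end data preparation: raw tables -> BLUEs, kernels, feature blocks.

Glues the stages together the way the analysis runs in practice: marker QC
and mean-imputation, within-environment grain-yield BLUEs with the DTH
covariate, per-band BLUEs, the three relationship kernels (G from markers,
P from standardized band BLUEs at line-by-environment resolution, K from
standardized 10-day EC features), and the observation table the
multi-environment models are fitted on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import ioqc, kernels, pheno_adjust

__all__ = ["PreparedData", "prepare_dataset"]


@dataclass
class PreparedData:
    """Everything the model-fitting and evaluation stages consume."""

    obs: pd.DataFrame            # index obs_id; columns line, env, y (GY BLUE)
    G: kernels.KernelMatrix      # line-level genomic kernel
    P_obs: kernels.KernelMatrix  # observation-level hyperspectral kernel
    K_env: kernels.KernelMatrix | None  # environment-level EC kernel
    band_blues: pd.DataFrame     # (line, env)-indexed band BLUEs
    markers_imputed: pd.DataFrame
    ec_features: pd.DataFrame | None
    qc_report: ioqc.QCReport


def prepare_dataset(markers: ioqc.MarkerMatrix, plots: pd.DataFrame,
                    weather: pd.DataFrame | None = None,
                    dth_covariate: bool = True,
                    bands: list | None = None) -> PreparedData:
    """Run QC, stage-1 adjustment and kernel construction on raw tables."""
    clean, report = ioqc.marker_qc(markers)
    imputed = ioqc.impute_missing(clean)

    gy = pheno_adjust.compute_blues(plots, scope="within_env",
                                    dth_covariate=dth_covariate, trait="GY")
    obs = gy.rename(columns={"estimate": "y"})[["line", "env", "y"]].copy()
    obs.index = [f"{l}@{e}" for l, e in zip(obs["line"], obs["env"])]
    obs.index.name = "obs_id"

    band_blues, _ = pheno_adjust.band_blues_and_h2(plots, bands=bands)
    bb = band_blues.set_index(["line", "env"])

    # observation-level hyperspectral kernel from standardized band BLUEs
    keys = list(zip(obs["line"], obs["env"]))
    S = bb.loc[keys]
    P_obs = kernels.linear_kernel(
        pd.DataFrame(S.to_numpy(float), index=obs.index, columns=S.columns),
        kind="P").ensure_psd()

    lines = sorted(plots["line"].unique())
    mk = imputed.to_dataframe().loc[lines]
    G = kernels.linear_kernel(mk, kind="G").ensure_psd()

    K_env = None
    ecs = None
    if weather is not None:
        ecs = ioqc.aggregate_ecs(weather)
        W = kernels.standardize_columns(ecs)
        K_env = kernels.linear_kernel(W, standardize=False, kind="K").ensure_psd()

    return PreparedData(obs=obs, G=G, P_obs=P_obs, K_env=K_env,
                        band_blues=bb, markers_imputed=mk,
                        ec_features=ecs, qc_report=report)
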