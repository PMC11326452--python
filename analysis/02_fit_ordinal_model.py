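#!/usr/bin/env python
"""Phase I: fit the proportional-odds model to the cohort.

Produces the model-fitting information (intercept-only vs final model,
likelihood-ratio chi-square) and the Wald coefficient table with odds
ratios, mirroring how ordinal-regression results are reported.
"""

import argparse
from pathlib import Path

import numpy as np

from polrboot.cli_report import (
    markdown_table,
    render_coefficient_table,
    render_model_fit_info,
)
from polrboot.data_model import DesignMatrix, encode_design, load_schema, read_dataset
from polrboot.fit_metrics import metrics_from_fits
from polrboot.polr_core import fit_polr, wald_table


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--cohort", type=Path, default=Path("results/cohort.csv"))
    parser.add_argument("--schema", type=Path, default=Path("results/schema.json"))
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()

    outcome, predictors = load_schema(args.schema)
    dataset = read_dataset(args.cohort, outcome, predictors)
    design = encode_design(dataset)
    fit_final = fit_polr(design)
    fit_null = fit_polr(
        DesignMatrix(
            columns=[],
            values=np.empty((design.n_obs, 0)),
            outcome_codes=design.outcome_codes,
            outcome_levels=design.outcome_levels,
        )
    )
    metrics = metrics_from_fits(fit_final, fit_null)

    info = render_model_fit_info(metrics)
    info.to_csv(args.outdir / "model_fit_info.csv", index=False)
    table = wald_table(fit_final)
    table.to_csv(args.outdir / "coefficients.csv")
    (args.outdir / "coefficients.md").write_text(
        markdown_table(render_coefficient_table(table))
    )

    print(f"n = {design.n_obs}, slope columns k = {design.k}")
    print(
        f"NLL: intercept-only {metrics.nll_null:.3f}, final {metrics.nll_final:.3f}; "
        f"LR chi-square {metrics.chi_square:.3f} on {metrics.df} df "
        f"(p = {metrics.p_value:.4f})"
    )
    print(
        f"AIC {metrics.aic:.3f}, BIC {metrics.bic:.3f}, "
        f"McFadden {metrics.mcfadden:.3f}, Cox-Snell {metrics.cox_snell:.3f}, "
        f"Nagelkerke {metrics.nagelkerke:.3f}"
    )
    print("\ncoefficients:")
    print(render_coefficient_table(table).to_string(index=False))


if __name__ == "__main__":
    main()
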