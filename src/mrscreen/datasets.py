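"""Bundled reference tables for lipid → immune-cell → ischemic-stroke MR.

Two small curated tables of reported two-sample MR results for plasma lipid
species, circulating immune-cell phenotypes and ischemic-stroke subtypes
(LAS = large artery stroke, SVS = small vessel stroke, CS = cardioembolic
stroke).  They serve the examples and the regression tests:

* :func:`mediation_pathways` — two-step MR decompositions (total, direct and
  indirect effects on the log-odds scale, and the reported proportion
  mediated in percent; NA where total and indirect effects disagree in sign);
* :func:`mr_diagnostics` — pleiotropy/heterogeneity diagnostics (MR-Egger
  intercept with its p-value, Cochran's Q with its p-value) for the
  significant exposure→outcome analyses of the same screen.

Values are rounded to the precision at which they were reported.
"""

from __future__ import annotations

from io import StringIO

import pandas as pd

__all__ = ["mediation_pathways", "mr_diagnostics"]

_MEDIATION_TSV = """\
exposure\tmediator\toutcome\ttotal\tdirect\tindirect\tproportion_pct
Phosphatidylcholine (18:2_0:0) levels\tFSC-A on granulocyte\tLAS\t-0.381\t-0.316\t-0.065\t17.05
Phosphatidylcholine (O-18:2_20:4) levels\tCCR2 on granulocyte\tLAS\t0.265\t0.193\t0.072\t27.06
Phosphatidylcholine (O-16:0_20:4) levels\tCD11c on CD62L+ myeloid Dendritic Cell\tLAS\t0.181\t0.163\t0.018\t10.05
Sterol ester (27:1/22:6) levels\tCD11c on CD62L+ myeloid Dendritic Cell\tLAS\t0.312\t0.283\t0.029\t9.34
Phosphatidylinositol (18:1_18:2) levels\tCD4 on activated CD4 regulatory T cell\tSVS\t-0.156\t-0.101\t-0.055\t35.05
Phosphatidylinositol (18:1_18:2) levels\tCD4 on activated & secreting CD4 regulatory T cell\tSVS\t-0.156\t-0.101\t-0.055\t35.35
Phosphatidylcholine (O-16:1_20:4) levels\tCD45RA+ CD28- CD8+ T cell absolute count\tCS\t-0.193\t-0.195\t0.002\tNA
Phosphatidylinositol (16:0_18:2) levels\tCD28 on CD39+ activated CD4 regulatory T cell\tCS\t-0.22\t-0.255\t0.035\tNA
Phosphatidylinositol (18:1_18:2) levels\tCD28 on CD39+ activated CD4 regulatory T cell\tCS\t-0.161\t-0.201\t0.040\tNA
Sphingomyelin (d40:2) levels\tCD8 on CD39+ CD8+ T cell\tCS\t0.132\t0.156\t-0.024\tNA
"""

_DIAGNOSTICS_TSV = """\
exposure\toutcome\tegger_intercept\tintercept_pval\tq\tq_pval
Sterol ester (27:1/16:0) levels\tLAS\t-0.016\t0.892\t3.578\t0.167
Sterol ester (27:1/18:0) levels\tLAS\t0.007\t0.889\t14.309\t0.056
Sterol ester (27:1/20:4) levels\tLAS\t-0.039\t0.118\t6.105\t0.191
Phosphatidylcholine (15:0_18:2) levels\tLAS\t0.014\t0.634\t9.290\t0.098
Phosphatidylcholine (16:0_18:2) levels\tLAS\t0.026\t0.253\t8.276\t0.219
Phosphatidylcholine (16:0_18:3) levels\tLAS\t-0.165\t0.870\t4.396\t0.111
Phosphatidylcholine (16:0_20:2) levels\tLAS\t0.025\t0.341\t2.585\t0.630
Phosphatidylcholine (16:1_18:2) levels\tLAS\t0.016\t0.362\t2.662\t0.850
Phosphatidylcholine (17:0_18:2) levels\tLAS\t0.035\t0.566\t0.719\t0.698
Phosphatidylcholine (18:0_18:2) levels\tLAS\t0.013\t0.830\t7.725\t0.102
Phosphatidylcholine (18:0_20:4) levels\tLAS\t-0.009\t0.703\t2.936\t0.402
Phosphatidylcholine (18:1_18:1) levels\tLAS\t0.031\t0.571\t4.183\t0.242
Phosphatidylcholine (18:1_18:2) levels\tLAS\t-0.007\t0.717\t3.478\t0.481
Phosphatidylcholine (18:1_20:2) levels\tLAS\t0.009\t0.834\t1.592\t0.451
Phosphatidylcholine (18:2_18:2) levels\tLAS\t0.035\t0.466\t2.353\t0.308
Phosphatidylethanolamine (16:0_18:2) levels\tLAS\t0.020\t0.599\t5.468\t0.361
Phosphatidylinositol (18:0_18:1) levels\tLAS\t-0.103\t0.317\t5.696\t0.223
Phosphatidylinositol (18:0_18:2) levels\tLAS\t0.028\t0.555\t2.435\t0.487
Phosphatidylinositol (18:0_20:3) levels\tLAS\t-0.013\t0.635\t1.363\t0.714
Sterol ester (27:1/18:3) levels\tSVS\t0.016\t0.669\t0.552\t0.759
Sterol ester (27:1/20:3) levels\tSVS\t0.011\t0.812\t0.341\t0.843
Phosphatidylcholine (18:0_20:3) levels\tSVS\t-0.014\t0.770\t0.235\t0.889
Phosphatidylcholine (O-16:1_20:3) levels\tSVS\t0.004\t0.945\t0.099\t0.952
Sphingomyelin (d32:1) levels\tCS\t0.001\t0.954\t0.993\t0.803
Sphingomyelin (d40:2) levels\tCS\t0.005\t0.843\t0.167\t0.920
Phosphatidylcholine (18:2_0:0) levels\tFSC-A on granulocyte\t-0.116\t0.663\t0.404\t0.817
Sphingomyelin (d40:2) levels\tCD8 on CD39+ CD8+ T cell\t0.064\t0.215\t7.588\t0.180
CD14- CD16- absolute count\tLAS\t-0.094\t0.449\t1.675\t0.433
CD3 on naive CD8+ T cell\tLAS\t-0.006\t0.816\t0.273\t0.965
CD3 on CD45RA+ CD4+ T cell\tLAS\t-0.005\t0.855\t0.414\t0.937
CD40 on CD14+ CD16- monocyte\tLAS\t-0.007\t0.872\t1.215\t0.545
CD39 on granulocyte\tLAS\t-0.014\t0.948\t1.912\t0.384
SSC-A on granulocyte\tLAS\t-0.018\t0.659\t2.121\t0.548
CD62L- monocyte %monocyte\tSVS\t-0.036\t0.837\t2.192\t0.334
BAFF-R on IgD+ CD38- naive B cell\tSVS\t0.008\t0.696\t0.456\t0.928
BAFF-R on IgD+ CD38- unswitched memory B cell\tSVS\t-0.010\t0.813\t1.424\t0.491
BAFF-R on IgD+ CD38+ B cell\tSVS\t0.001\t0.927\t0.574\t0.966
BAFF-R on IgD+ CD38dim B cell\tSVS\t0.008\t0.675\t0.405\t0.939
BAFF-R on IgD- CD24- B cell\tSVS\t-0.011\t0.530\t2.315\t0.510
BAFF-R on IgD- CD27- B cell\tSVS\t-0.011\t0.533\t2.258\t0.521
BAFF-R on transitional B cell\tSVS\t0.009\t0.674\t0.417\t0.937
BAFF-R on B cell\tSVS\t0.007\t0.666\t0.404\t0.982
CD33 on granulocytic myeloid-derived suppressor cells\tSVS\t0.005\t0.831\t0.684\t0.710
HLA DR on B cell\tSVS\t0.010\t0.724\t0.494\t0.781
CD28+ CD45RA+ CD8+ T cell absolute count\tCS\t-0.086\t0.416\t1.954\t0.376
CD45RA+ CD28- CD8+ T cell absolute count\tCS\t0.005\t0.636\t39.417\t0.541
BAFF-R on IgD+ CD24- B cell\tCS\t-0.002\t0.903\t1.976\t0.853
BAFF-R on IgD+ CD38- B cell\tCS\t-0.010\t0.624\t1.834\t0.766
BAFF-R on IgD+ CD38- naive B cell\tCS\t-0.004\t0.851\t1.968\t0.742
BAFF-R on IgD+ CD38+ B cell\tCS\t0.012\t0.422\t4.228\t0.517
BAFF-R on IgD+ CD38dim B cell\tCS\t-0.002\t0.911\t2.064\t0.840
BAFF-R on naive-mature B cell\tCS\t-0.003\t0.856\t2.062\t0.840
BAFF-R on transitional B cell\tCS\t-0.007\t0.741\t1.727\t0.786
CD25 on naive-mature B cell\tCS\t-0.001\t0.974\t0.043\t0.998
"""


def mediation_pathways() -> pd.DataFrame:
    """Reference two-step MR decompositions (10 pathways, 3 stroke subtypes)."""
    return pd.read_csv(StringIO(_MEDIATION_TSV), sep="\t", na_values=["NA"])


def mr_diagnostics() -> pd.DataFrame:
    """Reference pleiotropy/heterogeneity diagnostics (54 analyses)."""
    return pd.read_csv(StringIO(_DIAGNOSTICS_TSV), sep="\t")
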