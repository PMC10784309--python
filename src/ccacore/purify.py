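"""Cohort purification: tissue-template NTP plus pathologist contamination calls.

A sample goes to the *verification* cohort when it both resembles a normal
tissue template (NTP FDR <= 0.1 against liver/pancreas marker templates) and
carries a pathologist-estimated overall contamination fraction > 25%; all
other samples form the *purified* cohort used for class discovery.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cohortio import ExpressionMatrix, GeneSetCollection
from .subtype_classifier import NTPResult, TemplateSet, ntp_predict

__all__ = ["CohortSplit", "tissue_ntp", "stratify_cohort"]


@dataclass
class CohortSplit:
    """Disjoint purified/verification partition with per-sample reasons."""

    purified: list[str]
    verification: list[str]
    reasons: pd.DataFrame  # index sample_id: ntp_fdr, contamination_overall, cohort, rule_fired

    def __post_init__(self) -> None:
        if set(self.purified) & set(self.verification):
            raise ValueError("purified and verification cohorts overlap")


def tissue_ntp(
    expr: ExpressionMatrix,
    templates: GeneSetCollection | TemplateSet,
    n_perm: int = 1000,
    seed: int = 0,
) -> NTPResult:
    """NTP of each sample against normal-tissue marker templates.

    ``templates`` must hold at least two tissue marker sets (e.g. liver- and
    pancreas-specific genes); at least 5 genes per template must be present in
    the matrix.
    """
    if isinstance(templates, GeneSetCollection):
        templates = TemplateSet.from_collection(templates)
    return ntp_predict(expr, templates, n_perm=n_perm, seed=seed, min_overlap=5)


def stratify_cohort(
    ntp: NTPResult,
    clin: pd.DataFrame,
    fdr_max: float = 0.1,
    contamination_min: float = 0.25,
) -> CohortSplit:
    """Split the cohort by the combined NTP + contamination rule.

    verification iff (NTP FDR <= fdr_max) AND (contamination_overall >
    contamination_min); the FDR bound is inclusive, the contamination bound
    strict.  Every sample needs a clinical record with
    ``contamination_overall``.
    """
    if not 0 <= fdr_max <= 1:
        raise ValueError("fdr_max must be in [0, 1]")
    if "contamination_overall" not in clin.columns:
        raise ValueError("clinical table lacks contamination_overall")
    clin = clin.set_index("sample_id") if clin.index.name != "sample_id" else clin
    rows = []
    for sample in ntp.table.index:
        if sample not in clin.index:
            raise ValueError(f"sample {sample!r} has no clinical record")
        co = clin.loc[sample, "contamination_overall"]
        if pd.isna(co):
            raise ValueError(f"sample {sample!r} missing contamination_overall")
        fdr = float(ntp.table.loc[sample, "fdr"])
        tissue_like = fdr <= fdr_max
        contaminated = co > contamination_min
        if tissue_like and contaminated:
            cohort, rule = "verification", "ntp_fdr<=max AND contamination>min"
        elif tissue_like:
            cohort, rule = "purified", "contamination<=min"
        elif contaminated:
            cohort, rule = "purified", "ntp_fdr>max"
        else:
            cohort, rule = "purified", "neither condition"
        rows.append(
            {
                "sample_id": sample,
                "predicted_tissue": ntp.table.loc[sample, "predicted"],
                "distance": ntp.table.loc[sample, "distance"],
                "p": ntp.table.loc[sample, "p"],
                "ntp_fdr": fdr,
                "contamination_overall": float(co),
                "cohort": cohort,
                "rule_fired": rule,
            }
        )
    reasons = pd.DataFrame(rows).set_index("sample_id")
    purified = list(reasons.index[reasons["cohort"] == "purified"])
    verification = list(reasons.index[reasons["cohort"] == "verification"])
    return CohortSplit(purified, verification, reasons)
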