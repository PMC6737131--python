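import pytest

from epath.ko_tables import KOAnnotation

FATTY = "Fatty acid metabolism//Fatty acid biosynthesis//"
PARTNERS = [
    "K01716",
    "K18473",
    "K00645",
    "K02371",
    "K00648",
    "K10780",
    "K00667",
    "K00668",
]
PARTNER_SCORES = [0.90, 0.80, 0.70, 0.60, 0.50, 0.40, 0.36, 0.30]  # mean 0.57
EMPTY_COG_KOS = ["K20001", "K20002", "K20003", "K20004"]
EMPTY_COG_SCORES = [0.01, 0.02, 0.05, 0.08]  # mean 0.04


@pytest.fixture
def fatty_acid_annotations() -> dict[str, KOAnnotation]:
    """Annotation table mirroring the fatty-acid worked example: one unscored KO
    whose full pathway string matches eight scored partners (mean E_score 0.57)
    and whose COG cell is empty, plus a scored empty-COG group (mean 0.04)."""
    table = {
        "K10781": KOAnnotation(
            ko_id="K10781", kegg_pathway_annotation=FATTY, cog_annotation=""
        )
    }
    for k, ko in enumerate(PARTNERS):
        table[ko] = KOAnnotation(
            ko_id=ko,
            kegg_pathway_annotation=FATTY,
            cog_annotation=f"acyl carrier group {k}//",
        )
    for ko in EMPTY_COG_KOS:
        table[ko] = KOAnnotation(
            ko_id=ko,
            kegg_pathway_annotation="Unrelated pathway//",
            cog_annotation="",
        )
    return table


@pytest.fixture
def fatty_acid_e_scores() -> dict[str, float]:
    scores = dict(zip(PARTNERS, PARTNER_SCORES))
    scores.update(dict(zip(EMPTY_COG_KOS, EMPTY_COG_SCORES)))
    return scores
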