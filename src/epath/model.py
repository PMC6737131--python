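"""Model/Results layer tying the pipeline together.

``EssentialGeneModel`` holds the training inputs — per-strain gene tables,
the KO annotation table, and optionally one scored pathway graph per strain —
and ``fit()`` runs remapping, tallying and scoring in one pass, returning an
``EssentialGeneResults`` carrying the per-KO scores, the remapping output,
and prediction/evaluation methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import evaluation, ko_tables, remapping, scoring
from .exceptions import IntegrityError
from .kgml_io import PathwayGraph
from .ko_tables import EssentialityCounts, KOAnnotation, StrainGeneRecord
from .scoring import ScoreRecord, Thresholds


class EssentialGeneModel:
    """Essentiality scoring model over a multi-strain training panel.

    Parameters
    ----------
    strain_tables
        One gene table (list of StrainGeneRecord) per training strain.
    annotations
        KO annotation table keyed by KO id.
    pathways
        Optional map strain_id -> scored PathwayGraph; when given, the
        remapping search runs per strain and its recovered gap genes enter the
        tallies as missing-essential.
    """

    def __init__(
        self,
        strain_tables: list[list[StrainGeneRecord]],
        annotations: dict[str, KOAnnotation],
        pathways: dict[str, PathwayGraph] | None = None,
    ) -> None:
        if not strain_tables:
            raise IntegrityError("at least one strain table is required")
        self.strain_tables = strain_tables
        self.annotations = annotations
        self.pathways = pathways or {}
        known = {t[0].strain_id for t in strain_tables if t}
        unknown = set(self.pathways) - known
        if unknown:
            raise IntegrityError(f"pathways given for unknown strains: {sorted(unknown)}")

    @classmethod
    def from_files(
        cls,
        annotation_path,
        strain_paths: dict[str, str],
        pathway_graphs: dict[str, PathwayGraph] | None = None,
    ) -> "EssentialGeneModel":
        annotations = ko_tables.load_ko_annotations(annotation_path)
        tables = [
            ko_tables.load_strain_genes(path, sid)
            for sid, path in sorted(strain_paths.items())
        ]
        return cls(tables, annotations, pathway_graphs)

    def fit(self, mode: str = "raw_mean", match: str = "full") -> "EssentialGeneResults":
        """Remap, tally and score; returns the fitted results object."""
        remap_results = {
            sid: remapping.remap_strain(graph) for sid, graph in self.pathways.items()
        }
        remapped = {sid: res.missing_genes for sid, res in remap_results.items()}
        tallies = ko_tables.tally_ko_essentiality(self.strain_tables, remapped)
        scores = scoring.score_all(self.annotations, tallies, mode=mode, match=match)
        return EssentialGeneResults(
            model=self, tallies=tallies, scores=scores, remap_results=remap_results
        )


@dataclass
class EssentialGeneResults:
    """Fitted per-KO scores plus the remapping diagnostics behind them."""

    model: EssentialGeneModel
    tallies: dict[str, EssentialityCounts]
    scores: dict[str, ScoreRecord]
    remap_results: dict[str, remapping.RemapResult] = field(default_factory=dict)

    @property
    def scores_frame(self):
        return scoring.scores_to_frame(self.scores)

    def predict(
        self,
        genes: list[StrainGeneRecord],
        thresholds: Thresholds | None = None,
        rule: str = "e_priority",
    ) -> list[evaluation.PredictionRecord]:
        return evaluation.predict(self.scores, genes, thresholds, rule)

    def evaluate(
        self,
        genes: list[StrainGeneRecord],
        thresholds: Thresholds | None = None,
        rule: str = "e_priority",
    ):
        """Predict on a labeled validation table and return (confusion, metrics)."""
        preds = self.predict(genes, thresholds, rule)
        truth = {g.locus_tag: g.label for g in genes}
        cm = evaluation.confusion(preds, truth)
        return cm, evaluation.metrics(cm)

    def summary(self) -> str:
        lines = ["Essential-gene scoring results", "=" * 34]
        n_strains = len(self.model.strain_tables)
        lines.append(f"training strains:        {n_strains}")
        lines.append(f"KOs scored:              {len(self.scores)}")
        direct = sum(1 for r in self.scores.values() if r.e_score_source == "direct")
        linked = sum(
            1 for r in self.scores.values() if r.e_score_source == "reaction_linked"
        )
        lines.append(f"E_score direct/linked:   {direct}/{linked}")
        n_p = sum(1 for r in self.scores.values() if r.p_score is not None)
        lines.append(f"P_score assigned:        {n_p}")
        for sid, res in sorted(self.remap_results.items()):
            lines.append(
                f"remapping [{sid}]:         {len(res.missing_edges)} gap edges, "
                f"{len(res.missing_genes)} gap genes"
            )
        summ = scoring.summarize_scores(self.scores)
        lines.append("")
        lines.append(summ.round(3).to_string())
        return "\n".join(lines)
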