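"""Per-KO essentiality scores: E_score from experimental tallies, P_score from annotation groups.

E_score for a KO with tallies (eg_e, eg_m, non_eg) over N training strains is

    E = ((eg_e + eg_m) / (eg_e + eg_m + non_eg + 1))^2
        * ((eg_e + eg_m + non_eg) / N)

the squared essentiality frequency among appearing strains (with +1
shrinkage) times the appearance frequency. It lives in [0, (N/(N+1))^2); with
the standard 31-strain training panel the ceiling rounds to 0.938.

P_score transfers E_scores to un-tallied KOs through shared annotation: a
KO's P_score_KEGG (P_score_COG) is the mean E_score of the other KOs whose
full KEGG pathway (COG) annotation string matches its own exactly, and
P_score averages the two components. KOs with an empty annotation string form
their own group; a KO with neither annotation gets no P_score.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import mean

from .exceptions import ConfigError, EPathError
from .ko_tables import EssentialityCounts, KOAnnotation

E_SCORE_SOURCES = ("direct", "reaction_linked", "absent")


@dataclass(frozen=True)
class Thresholds:
    """Decision thresholds: a KO is called essential when E_score >= tau_e, or
    failing an E_score, when P_score >= tau_p."""

    tau_e: float = 0.6
    tau_p: float = 0.03

    def __post_init__(self) -> None:
        for name, v in (("tau_e", self.tau_e), ("tau_p", self.tau_p)):
            if not (0.0 < v < 1.0):
                raise ConfigError(f"{name} must be in (0, 1), got {v}")


@dataclass
class ScoreRecord:
    ko_id: str
    e_score: float | None = None
    p_score_kegg: float | None = None
    p_score_cog: float | None = None
    p_score: float | None = None
    e_score_source: str = "absent"


def e_score(counts: EssentialityCounts) -> float:
    """Evaluate the experimental essentiality score for one KO tally."""
    if counts.n_strains < 1:
        raise EPathError("n_strains must be >= 1")
    ess = counts.eg_e + counts.eg_m
    appear = ess + counts.non_eg
    return (ess / (appear + 1)) ** 2 * (appear / counts.n_strains)


def _annotation_string(ann: KOAnnotation, key: str) -> str:
    if key == "kegg_pathway":
        return ann.kegg_pathway_annotation
    if key == "cog":
        return ann.cog_annotation
    raise ConfigError(f"unknown grouping key {key!r}")


def _tokens(value: str) -> frozenset[str]:
    return frozenset(t for t in value.split("//") if t.strip())


def group_mean_score(
    ko_id: str,
    key: str,
    annotations: dict[str, KOAnnotation],
    e_scores: dict[str, float],
    match: str = "full",
) -> float:
    """Mean E_score of the KO's annotation group under ``key``.

    The group is every other KO whose annotation string under ``key`` is
    byte-identical (``match="full"``, the default; the empty string forms its
    own group) or shares at least one "//" token (``match="token"``). The KO
    itself is excluded. Returns 0 when no group member has an E_score.
    """
    if ko_id not in annotations:
        raise KeyError(f"KO {ko_id} not in annotation table")
    if match not in ("full", "token"):
        raise ConfigError(f"unknown match mode {match!r}")
    own = _annotation_string(annotations[ko_id], key)
    own_tokens = _tokens(own)
    values: list[float] = []
    for other, ann in annotations.items():
        if other == ko_id:
            continue
        theirs = _annotation_string(ann, key)
        if match == "full":
            hit = theirs == own
        else:
            hit = bool(_tokens(theirs) & own_tokens) or (not own_tokens and not _tokens(theirs))
        if hit and other in e_scores and e_scores[other] is not None:
            values.append(e_scores[other])
    return mean(values) if values else 0.0


def p_score(
    p_kegg: float | None, p_cog: float | None, mode: str = "raw_mean"
) -> float | None:
    """Combine the two annotation-group components into one P_score.

    ``raw_mean`` averages the present components directly (both already live
    on [0, 1]); an absent pair yields an absent score. Min-max standardization
    is a population-level rescale and is applied in :func:`score_all`.
    """
    if mode not in ("raw_mean", "minmax_standardized"):
        raise ConfigError(f"unknown P_score mode {mode!r}")
    present = [v for v in (p_kegg, p_cog) if v is not None]
    if not present:
        return None
    return mean(present)


def _minmax(values: dict[str, float]) -> dict[str, float]:
    if not values:
        return {}
    lo, hi = min(values.values()), max(values.values())
    if hi == lo:
        return {k: 0.0 for k in values}
    return {k: (v - lo) / (hi - lo) for k, v in values.items()}


def score_all(
    annotations: dict[str, KOAnnotation],
    tallies: dict[str, EssentialityCounts],
    mode: str = "raw_mean",
    match: str = "full",
) -> dict[str, ScoreRecord]:
    """Score every KO appearing in the annotation table or the tallies.

    Tallied KOs get a direct E_score. An annotated but un-tallied KO that
    shares a reaction identifier with tallied KOs inherits the mean of its
    link partners' E_scores (flagged ``reaction_linked``). P_score components
    are computed for every annotated KO unless both annotation strings are
    empty, in which case all P fields stay absent.
    """
    if mode not in ("raw_mean", "minmax_standardized"):
        raise ConfigError(f"unknown P_score mode {mode!r}")

    e_scores: dict[str, float] = {}
    sources: dict[str, str] = {}
    for ko, counts in tallies.items():
        e_scores[ko] = e_score(counts)
        sources[ko] = "direct"

    # reaction-linked inheritance for annotated KOs with no tally of their own
    reaction_partners: dict[str, list[str]] = {}
    for ko, ann in annotations.items():
        if ko in e_scores or not ann.reaction_ids:
            continue
        partners = [
            other
            for other, oann in annotations.items()
            if other in e_scores
            and sources.get(other) == "direct"
            and oann.reaction_ids & ann.reaction_ids
        ]
        if partners:
            reaction_partners[ko] = partners
    for ko, partners in reaction_partners.items():
        e_scores[ko] = mean(e_scores[p] for p in partners)
        sources[ko] = "reaction_linked"

    p_kegg: dict[str, float] = {}
    p_cog: dict[str, float] = {}
    for ko, ann in annotations.items():
        if not ann.kegg_pathway_annotation and not ann.cog_annotation:
            continue
        p_kegg[ko] = group_mean_score(ko, "kegg_pathway", annotations, e_scores, match)
        p_cog[ko] = group_mean_score(ko, "cog", annotations, e_scores, match)

    if mode == "minmax_standardized":
        kegg_std, cog_std = _minmax(p_kegg), _minmax(p_cog)
    else:
        kegg_std, cog_std = p_kegg, p_cog

    records: dict[str, ScoreRecord] = {}
    for ko in sorted(set(annotations) | set(tallies)):
        pk = kegg_std.get(ko)
        pc = cog_std.get(ko)
        records[ko] = ScoreRecord(
            ko_id=ko,
            e_score=e_scores.get(ko),
            p_score_kegg=pk,
            p_score_cog=pc,
            p_score=p_score(pk, pc, "raw_mean"),
            e_score_source=sources.get(ko, "absent"),
        )
    return records


def summarize_scores(records: dict[str, ScoreRecord]):
    """Distribution summary (min/max/mean/sd and percentiles) of both scores."""
    import numpy as np
    import pandas as pd

    out = {}
    for name in ("e_score", "p_score"):
        vals = np.array(
            [getattr(r, name) for r in records.values() if getattr(r, name) is not None],
            dtype=float,
        )
        if vals.size == 0:
            out[name] = {"n": 0}
            continue
        out[name] = {
            "n": int(vals.size),
            "min": float(vals.min()),
            "max": float(vals.max()),
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
            "p50": float(np.percentile(vals, 50)),
            "p90": float(np.percentile(vals, 90)),
        }
    return pd.DataFrame(out).T


def scores_to_frame(records: dict[str, ScoreRecord]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "ko_id": r.ko_id,
                "e_score": r.e_score,
                "p_score_kegg": r.p_score_kegg,
                "p_score_cog": r.p_score_cog,
                "p_score": r.p_score,
                "e_score_source": r.e_score_source,
            }
            for r in records.values()
        ]
    )


def write_scores(records: dict[str, ScoreRecord], path) -> None:
    scores_to_frame(records).to_csv(path, sep="\t", index=False)


def load_scores(path) -> dict[str, ScoreRecord]:
    import pandas as pd

    frame = pd.read_csv(path, sep="\t", dtype={"ko_id": str})
    out: dict[str, ScoreRecord] = {}
    for row in frame.itertuples(index=False):
        def _opt(v):
            return None if pd.isna(v) else float(v)

        out[row.ko_id] = ScoreRecord(
            ko_id=row.ko_id,
            e_score=_opt(row.e_score),
            p_score_kegg=_opt(row.p_score_kegg),
            p_score_cog=_opt(row.p_score_cog),
            p_score=_opt(row.p_score),
            e_score_source=str(row.e_score_source),
        )
    return out
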