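"""End-to-end deisotoping: search -> graph -> score -> path -> ions.

Per spectrum, the stages compose as

    find_peak_sets -> enumerate_clusters -> build_graph
        -> assign_weights(ClusterScorer) -> highest_score_path
        -> select_ions

applied independently to each isotopic peak set.  Spectra are processed
independently and deterministically.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Any, Sequence

import yaml

from .cluster_search import SearchParams, enumerate_clusters, find_peak_sets
from .constants import DEFAULT_CONSTANTS, MassConstants
from .features import ClusterScorer, FeatureParams, ScoreWeights
from .graph import assign_weights, build_graph
from .path_search import PathResult, highest_score_path, select_ions
from .spectrum import DeisotopedIon, Spectrum

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "deisotope_spectrum", "deisotope_spectra", "SpectrumReport"]


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable constants of the pipeline in one place.

    Defaults are the method's printed constants: isotope gap 1.003 Da with
    tolerance 0.01, feature window θ = 0.3 Da, envelope threshold 0.3 and
    weights ω = (0.8, 0.5, 0.1, 0.1, 0.1).
    """

    search: SearchParams = field(default_factory=SearchParams)
    features: FeatureParams = field(default_factory=FeatureParams)
    weights: ScoreWeights = field(default_factory=ScoreWeights)
    constants: MassConstants = DEFAULT_CONSTANTS
    keep_singletons: bool = True
    intensity_split: str = "full"
    output_charge_mode: str = "native"

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        """Load overrides from a YAML mapping of section -> key -> value.

        Sections: ``search`` (iso_gap, gap_tolerance, charges, ...),
        ``feature`` (theta, f5_threshold, f2_offset_mode), ``weights``
        (w1..w5), ``path`` (keep_singletons, intensity_split), ``io``
        (output_charge_mode).
        """
        with open(path) as handle:
            raw: dict[str, Any] = yaml.safe_load(handle) or {}
        search_kw = dict(raw.get("search", {}))
        if "charges" in search_kw:
            search_kw["charges"] = frozenset(int(z) for z in search_kw["charges"])
        feature_kw = raw.get("feature", {})
        weight_kw = raw.get("weights", {})
        path_kw = raw.get("path", {})
        io_kw = raw.get("io", {})
        return cls(
            search=SearchParams(**search_kw),
            features=FeatureParams(**feature_kw),
            weights=ScoreWeights(**weight_kw),
            keep_singletons=bool(path_kw.get("keep_singletons", True)),
            intensity_split=str(path_kw.get("intensity_split", "full")),
            output_charge_mode=str(io_kw.get("output_charge_mode", "native")),
        )

    def replace(self, **kwargs: Any) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class SpectrumReport:
    """Per-spectrum processing summary."""

    title: str
    n_peaks: int
    n_sets: int
    n_candidates: int
    n_selected: int
    total_score: float


def deisotope_spectrum(
    spectrum: Spectrum,
    config: PipelineConfig = PipelineConfig(),
) -> list[DeisotopedIon]:
    """Deconvolve one spectrum into monoisotopic fragment ions."""
    ions, _ = deisotope_spectrum_with_report(spectrum, config)
    return ions


def deisotope_spectrum_with_report(
    spectrum: Spectrum,
    config: PipelineConfig = PipelineConfig(),
) -> tuple[list[DeisotopedIon], SpectrumReport]:
    if len(spectrum) == 0:
        return [], SpectrumReport(spectrum.title, 0, 0, 0, 0, 0.0)
    try:
        peak_sets, _ = find_peak_sets(spectrum, config.search)
        scorer = ClusterScorer(spectrum, config.weights, config.constants, config.features)
        results: list[PathResult] = []
        scores: dict[tuple[tuple[int, ...], int], float] = {}
        n_candidates = 0
        for peak_set in peak_sets:
            clusters = enumerate_clusters(peak_set, config.search)
            n_candidates += len(clusters)
            if not clusters:
                continue
            graph = build_graph(clusters)
            assign_weights(graph, scorer.score)
            result = highest_score_path(graph)
            results.append(result)
            for cluster in result.clusters:
                scores[(cluster.member_indices, cluster.charge)] = scorer.score(cluster)
        ions = select_ions(
            spectrum, results,
            keep_singletons=config.keep_singletons,
            intensity_split=config.intensity_split,
            cluster_scores=scores,
        )
        report = SpectrumReport(
            title=spectrum.title,
            n_peaks=len(spectrum),
            n_sets=len(peak_sets),
            n_candidates=n_candidates,
            n_selected=sum(len(r.clusters) for r in results),
            total_score=sum(r.total_score for r in results),
        )
        return ions, report
    except Exception as exc:
        raise RuntimeError(f"deisotoping failed for spectrum '{spectrum.title}'") from exc


def deisotope_spectra(
    spectra: Sequence[Spectrum],
    config: PipelineConfig = PipelineConfig(),
) -> tuple[list[tuple[Spectrum, list[DeisotopedIon]]], list[SpectrumReport]]:
    """Process spectra independently, preserving input order."""
    out = []
    reports = []
    for spectrum in spectra:
        ions, report = deisotope_spectrum_with_report(spectrum, config)
        out.append((spectrum, ions))
        reports.append(report)
        logger.debug("%s: %d peaks -> %d ions", spectrum.title, len(spectrum), len(ions))
    return out, reports
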