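"""End-to-end identification: Q-peaks in, ranked guests + model + contacts out.

The pipeline chains the library stages: height-filter and cluster the peaks,
rank every candidate against each cluster, build a carbon model for the top
candidate of the best cluster, suggest element reassignments, classify
host–guest contacts and compute the symmetry-clash occupancy cap.  Outputs
are deterministic for fixed inputs and configuration (reports carry no
timestamps; the run log records version, config hash and input hashes).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

from . import __version__
from .builder import (
    GuestModel,
    apply_suggestions,
    place_guest_as_carbons,
    polish_checklist,
    suggest_atom_types,
)
from .candidates import CandidateSet, default_candidates
from .interactions import InteractionParams, classify_contacts, occupancy_cap
from .io import ranking_to_dict, write_ins_model, write_report
from .matching import MatcherParams, Ranking, filter_and_cluster, rank_candidates
from .structures import HostStructure, QPeakSet

__all__ = ["PipelineConfig", "IdentifyResult", "NoIdentificationError", "identify", "load_config"]


class NoIdentificationError(RuntimeError):
    """No cluster large enough to attempt identification."""


@dataclass(frozen=True)
class PipelineConfig:
    """Validated configuration for an identification run."""

    matcher: MatcherParams = field(default_factory=MatcherParams)
    interaction: InteractionParams = field(default_factory=InteractionParams)
    rmsd_only: bool = False  # rank by raw RMSD (coverage_weight forced to 0)
    min_cluster_size: int = 2
    seed: int = 0

    def effective_matcher(self) -> MatcherParams:
        if not self.rmsd_only:
            return self.matcher
        return MatcherParams(
            bond_window=self.matcher.bond_window,
            height_min=self.matcher.height_min,
            pair_tol=self.matcher.pair_tol,
            min_coverage=self.matcher.min_coverage,
            coverage_weight=0.0,
            tie_tol=self.matcher.tie_tol,
        )


def load_config(data: dict) -> PipelineConfig:
    """Build a PipelineConfig from a nested mapping, rejecting unknown keys."""
    allowed = {f.name for f in fields(PipelineConfig)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")

    def sub(cls, key):
        payload = dict(data.get(key, {}))
        names = {f.name for f in fields(cls)}
        bad = set(payload) - names
        if bad:
            raise ValueError(f"unknown {key} config keys: {sorted(bad)}")
        for name, value in payload.items():
            if isinstance(value, list):
                payload[name] = tuple(value)
        return cls(**payload)

    return PipelineConfig(
        matcher=sub(MatcherParams, "matcher"),
        interaction=sub(InteractionParams, "interaction"),
        rmsd_only=bool(data.get("rmsd_only", False)),
        min_cluster_size=int(data.get("min_cluster_size", 2)),
        seed=int(data.get("seed", 0)),
    )


@dataclass
class IdentifyResult:
    rankings: list[Ranking]  # one per cluster, largest cluster first
    model: GuestModel
    reassignments: list[tuple[str, str]]
    interactions: list
    occupancy_cap: float
    unexplained_peaks: list[str]
    cluster_sizes: list[int]

    @property
    def top_candidate(self) -> str:
        return self.rankings[0].top().candidate_name


def identify(
    host: HostStructure,
    qpeaks: QPeakSet,
    candidates: CandidateSet | None = None,
    config: PipelineConfig = PipelineConfig(),
    out_dir: str | Path | None = None,
    input_hashes: dict[str, str] | None = None,
) -> IdentifyResult:
    """Run the full identification workflow; optionally write report files.

    Raises :class:`NoIdentificationError` when no peak cluster reaches
    ``min_cluster_size``.  With ``out_dir`` set, writes ``ranking.json``,
    ``model.ins``, ``checklist.json``, ``interactions.json`` and
    ``run_log.json``."""
    if candidates is None:
        candidates = default_candidates(seed=config.seed) if config.seed else default_candidates()
    params = config.effective_matcher()

    clusters = filter_and_cluster(qpeaks, params)
    clusters = [c for c in clusters if len(c) >= config.min_cluster_size]
    if not clusters:
        raise NoIdentificationError(
            f"no peak cluster of size >= {config.min_cluster_size} after filtering"
        )

    rankings = [rank_candidates(c, candidates, params) for c in clusters]
    top_entry = rankings[0].top()
    if top_entry.result is None:
        raise NoIdentificationError("no candidate achieved an admissible match")

    best_cluster = clusters[0]
    candidate = candidates.get(top_entry.candidate_name)
    model = place_guest_as_carbons(top_entry.result, best_cluster, host, candidate)
    reassignments = suggest_atom_types(model)

    matched = set(top_entry.result.matched_peak_labels)
    all_labels = {p.label for p in qpeaks.peaks}
    unexplained = sorted(all_labels - matched)

    # contacts are chemistry-dependent, so classify with final elements
    final_model = apply_suggestions(model)
    contacts = classify_contacts(host, final_model, config.interaction)
    cap = occupancy_cap(host, final_model, config.interaction)

    result = IdentifyResult(
        rankings=rankings,
        model=model,
        reassignments=reassignments,
        interactions=contacts,
        occupancy_cap=cap,
        unexplained_peaks=unexplained,
        cluster_sizes=[len(c) for c in clusters],
    )
    if out_dir is not None:
        _write_outputs(result, host, config, Path(out_dir), input_hashes or {})
    return result


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()


def _write_outputs(
    result: IdentifyResult,
    host: HostStructure,
    config: PipelineConfig,
    out_dir: Path,
    input_hashes: dict[str, str],
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_report(result.rankings[0], out_dir / "ranking.json")
    if len(result.rankings) > 1:
        extra = [ranking_to_dict(r) for r in result.rankings[1:]]
        (out_dir / "ranking_other_clusters.json").write_text(
            json.dumps(extra, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
    write_ins_model(host, result.model.atoms, out_dir / "model.ins")
    (out_dir / "checklist.json").write_text(
        json.dumps(
            polish_checklist(result.model, result.unexplained_peaks), indent=2, sort_keys=True
        )
        + "\n",
        encoding="utf-8",
    )
    (out_dir / "interactions.json").write_text(
        json.dumps(
            {
                "occupancy_cap": result.occupancy_cap,
                "contacts": [
                    {
                        "kind": it.kind,
                        "guest_atom": it.guest_atom,
                        "host_atom": it.host_atom,
                        "distance": round(it.distance, 6),
                        "symop": it.symop,
                    }
                    for it in result.interactions
                ],
            },
            indent=2,
            sort_keys=True,
        )
        + "\n",
        encoding="utf-8",
    )
    (out_dir / "run_log.json").write_text(
        json.dumps(
            {
                "version": __version__,
                "config": asdict(config),
                "config_hash": _config_hash(config),
                "input_hashes": input_hashes,
                "cluster_sizes": result.cluster_sizes,
                "top_candidate": result.top_candidate,
            },
            indent=2,
            sort_keys=True,
            default=str,
        )
        + "\n",
        encoding="utf-8",
    )
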