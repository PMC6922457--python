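"""End-to-end corpus analysis: scores -> encodings -> TP models -> PCA and
entropy correlations, with CSV/JSON result tables.

Two named run templates mirror the two corpus designs:

``study1``
    Aggregation units are multi-movement works: per-movement TP models are
    pooled per unit, the PCA reports 2 components, and melody/bass entropy
    correlations pool all units.

``study2``
    Units are keys covered by several pieces (e.g. prelude/fugue across two
    books): the PCA reports 3 components, entropy correlations are split by
    tonal mode, and a tonic-paired major-vs-minor correlation is added.

Reruns with the same config and inputs are byte-identical: outputs carry a
config hash instead of timestamps and all floats print at fixed precision.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .components import (FeatureMatrix, PCAResult, build_feature_matrix,
                         interpret_components, pca_correlation)
from .encoding import WINDOW, windows
from .entropy_stats import (CorrelationResult, correlations_frame, entropy_table,
                            melody_bass_correlations, mode_paired_correlation)
from .exceptions import VoiceTPError
from .markov import (BY_TRANSITIONS, EntropyRecord, TPDistribution,
                     conditional_entropy, estimate_tp, pool_tp, tp_long_records)
from .score_io import BASS, MELODY, VoiceLine, load_corpus

log = logging.getLogger(__name__)

STUDY1, STUDY2 = "study1", "study2"
_TEMPLATE_DEFAULTS = {STUDY1: {"n_report": 2, "mode_split": False, "paired_modes": False},
                      STUDY2: {"n_report": 3, "mode_split": True, "paired_modes": True}}


@dataclass
class RunConfig:
    """Everything a run needs; hashable to a reproducibility fingerprint."""

    manifest: str | Path
    template: str = STUDY1
    orders: tuple[int, ...] = (0, 1, 2, 3, 4, 5)
    convention: str = WINDOW
    pooling: str = BY_TRANSITIONS
    value_kind: str = "tp"
    n_report: int | None = None
    mode_split: bool | None = None
    paired_modes: bool | None = None
    pooled_pair_voices: bool = False
    alpha: float = 0.05
    keyboard_range: tuple[int, int] = (0, 127)
    on_parse_error: str = "abort"
    out_dir: str | Path | None = None
    write_tp_table: bool = True
    seed: int = 0

    def resolved(self) -> "RunConfig":
        if self.template not in _TEMPLATE_DEFAULTS:
            raise VoiceTPError(f"unknown template {self.template!r}")
        if not set(self.orders) <= set(range(6)):
            raise VoiceTPError("orders must be a subset of 0..5")
        if not 0.0 < self.alpha < 1.0:
            raise VoiceTPError("alpha must be in (0, 1)")
        defaults = _TEMPLATE_DEFAULTS[self.template]
        return dataclasses.replace(
            self,
            n_report=self.n_report if self.n_report is not None else defaults["n_report"],
            mode_split=self.mode_split if self.mode_split is not None else defaults["mode_split"],
            paired_modes=(self.paired_modes if self.paired_modes is not None
                          else defaults["paired_modes"]),
        )

    def config_hash(self) -> str:
        payload = {k: (str(v) if isinstance(v, Path) else v)
                   for k, v in dataclasses.asdict(self).items() if k != "out_dir"}
        return hashlib.sha1(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


@dataclass
class AnalysisResult:
    config: RunConfig
    entropy_records: list[EntropyRecord]
    entropy: pd.DataFrame
    modes: dict[str, str]
    pooled: dict[int, dict[tuple[str, str], TPDistribution]]
    features: dict[int, FeatureMatrix]
    pca: dict[int, PCAResult]
    interpretations: dict[int, list[dict[str, object]]]
    correlations: list[CorrelationResult]
    tp_table: pd.DataFrame | None = None
    output_files: list[Path] = field(default_factory=list)


def run_analysis(cfg: RunConfig) -> AnalysisResult:
    """Execute the full analysis described by ``cfg``.

    Stages: score reading -> voice extraction -> interval encoding -> per-piece
    TP estimation -> per-unit pooling -> entropy table -> per-order PCA ->
    correlation analyses -> (optionally) CSV/JSON outputs.  Any stage error
    aborts with the stage and offending unit named; no partial output files
    are left behind.
    """
    cfg = cfg.resolved()
    units = load_corpus(cfg.manifest, on_parse_error=cfg.on_parse_error,
                        keyboard_range=cfg.keyboard_range)
    return analyze_lines(units, cfg)


def analyze_lines(
    units: Mapping[str, list[tuple[VoiceLine, VoiceLine]]],
    cfg: RunConfig,
) -> AnalysisResult:
    """Run the post-score stages on already-extracted voice-line pairs."""
    cfg = cfg.resolved()
    modes: dict[str, str] = {}
    for unit_id, pieces in units.items():
        modes[unit_id] = pieces[0][0].mode if pieces else "unknown"

    # per-unit pooled TP models and entropies, per order
    pooled: dict[int, dict[tuple[str, str], TPDistribution]] = {o: {} for o in cfg.orders}
    records: list[EntropyRecord] = []
    for unit_id, pieces in units.items():
        for voice_idx, voice in ((0, MELODY), (1, BASS)):
            lines = [pair[voice_idx] for pair in pieces]
            for order in cfg.orders:
                try:
                    dists = [
                        estimate_tp(
                            windows(ln.pitches, order, cfg.convention, ln.piece_id),
                            order)
                        for ln in lines
                    ]
                    unit_dist = pool_tp(dists, method=BY_TRANSITIONS) \
                        if cfg.pooling == BY_TRANSITIONS else \
                        pool_tp(dists, weights=[d.n_transitions for d in dists],
                                method=cfg.pooling)
                except VoiceTPError as exc:
                    raise VoiceTPError(
                        f"stage markov failed for unit {unit_id!r} voice {voice} "
                        f"order {order}: {exc}") from exc
                pooled[order][(unit_id, voice)] = unit_dist
                if unit_dist.n_transitions >= 1:
                    records.append(EntropyRecord(
                        unit_id=unit_id, voice=voice, mode=modes[unit_id],
                        order=order, H=conditional_entropy(unit_dist)))
                else:
                    log.warning("unit %s voice %s has no order-%d transitions; "
                                "entropy cell left missing", unit_id, voice, order)

    table = entropy_table(records)

    features: dict[int, FeatureMatrix] = {}
    pca: dict[int, PCAResult] = {}
    interpretations: dict[int, list[dict[str, object]]] = {}
    for order in cfg.orders:
        dists = {k: d for k, d in pooled[order].items() if d.n_transitions >= 1}
        if len(dists) < 2:
            log.warning("order %d: fewer than 2 nonempty columns; PCA skipped", order)
            continue
        dropped = set(pooled[order]) - set(dists)
        if dropped:
            log.warning("order %d: dropping empty columns %s", order, sorted(dropped))
        col_modes = {k: modes[k[0]] for k in dists}
        try:
            fm = build_feature_matrix(dists, value_kind=cfg.value_kind, modes=col_modes)
            res = pca_correlation(fm)
        except VoiceTPError as exc:
            raise VoiceTPError(f"stage components failed at order {order}: {exc}") from exc
        features[order] = fm
        pca[order] = res
        interpretations[order] = interpret_components(
            res, modes=fm.modes, n_components=min(cfg.n_report, res.loadings.shape[1]))

    try:
        correlations = melody_bass_correlations(
            table, modes=modes, split_by_mode=cfg.mode_split, orders=cfg.orders)
        if cfg.paired_modes:
            correlations += mode_paired_correlation(
                table, modes, orders=cfg.orders, pooled_voices=cfg.pooled_pair_voices)
    except VoiceTPError as exc:
        raise VoiceTPError(f"stage entropy_stats failed: {exc}") from exc

    tp_table = None
    if cfg.write_tp_table:
        rows: list[dict[str, object]] = []
        for order in cfg.orders:
            for (unit_id, voice), d in pooled[order].items():
                rows.extend(tp_long_records(d, unit_id, voice))
        tp_table = pd.DataFrame(rows)

    result = AnalysisResult(
        config=cfg, entropy_records=records, entropy=table, modes=modes,
        pooled=pooled, features=features, pca=pca,
        interpretations=interpretations, correlations=correlations,
        tp_table=tp_table)
    if cfg.out_dir is not None:
        _write_outputs(result)
    return result


def _write_outputs(result: AnalysisResult) -> None:
    cfg = result.config
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    header = f"# voicetp {__version__} config={cfg.config_hash()}\n"
    written: list[Path] = []

    def write_csv(name: str, df: pd.DataFrame, index: bool = False) -> None:
        path = out_dir / name
        with open(path, "w", newline="") as fh:
            fh.write(header)
            df.to_csv(fh, index=index, float_format="%.6f", lineterminator="\n")
        written.append(path)

    try:
        ent = pd.DataFrame(
            [{"unit_id": r.unit_id, "voice": r.voice, "mode": r.mode,
              "order": r.order, "H_bits": r.H} for r in result.entropy_records])
        write_csv("entropy.csv", ent)

        eig_rows = []
        for order, res in result.pca.items():
            for k in range(len(res.eigenvalues)):
                eig_rows.append({"order": order, "component": k + 1,
                                 "eigenvalue": res.eigenvalues[k],
                                 "variance_pct": res.variance_pct[k],
                                 "cumulative_pct": res.cumulative_pct[k]})
        write_csv("pca_eigenvalues.csv", pd.DataFrame(eig_rows))

        load_rows = []
        for order, res in result.pca.items():
            fm = result.features[order]
            for (unit_id, voice) in res.loadings.index:
                for k in range(min(cfg.n_report, res.loadings.shape[1])):
                    load_rows.append({
                        "order": order, "component": k + 1, "unit_id": unit_id,
                        "voice": voice, "mode": fm.modes[(unit_id, voice)],
                        "loading": res.loadings.loc[(unit_id, voice), f"PC{k + 1}"]})
        write_csv("pca_loadings.csv", pd.DataFrame(load_rows))

        write_csv("correlations.csv",
                  correlations_frame(result.correlations, alpha=cfg.alpha))

        if result.tp_table is not None:
            write_csv("tp_long.csv", result.tp_table)

        interp_path = out_dir / "components.json"
        with open(interp_path, "w") as fh:
            json.dump({"config_hash": cfg.config_hash(),
                       "voicetp": __version__,
                       "interpretations": {str(o): v for o, v in
                                           result.interpretations.items()}},
                      fh, indent=2, sort_keys=True)
            fh.write("\n")
        written.append(interp_path)

        log_path = out_dir / "run_log.txt"
        with open(log_path, "w") as fh:
            fh.write(header)
            cfg_dict = {k: str(v) for k, v in dataclasses.asdict(cfg).items()
                        if k != "out_dir"}
            fh.write(json.dumps(cfg_dict, indent=2, sort_keys=True) + "\n")
            for unit_id, mode in result.modes.items():
                n_rec = sum(1 for r in result.entropy_records if r.unit_id == unit_id)
                fh.write(f"unit {unit_id} mode={mode} entropy_cells={n_rec}\n")
        written.append(log_path)
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise
    result.output_files = written
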