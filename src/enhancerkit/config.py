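"""Pipeline configuration: thresholds, study sizes, seed.

Defaults equal the published analysis cut-offs: sharp-peak p < 1e-6,
broad-domain window 200 / gap 200 / FDR 0.01, differential fold 2 with
p < 1e-4, expression detection alpha 0.05 with floor 1 and twofold
calls, distal threshold 2 kb, motif flank 2 kb.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .synth import StudyParams


@dataclass
class PipelineConfig:
    seed: int = 0
    # peak calling
    sharp_p: float = 1e-6
    broad_window: int = 200
    broad_gap: int = 200
    broad_fdr: float = 0.01
    # differential enrichment
    diff_fold: float = 2.0
    diff_p: float = 1e-4
    # expression
    expr_fold: float = 2.0
    detection_alpha: float = 0.05
    expr_floor: float = 1.0
    # enhancer construction
    distal_min: int = 2000
    min_enhancer_span: int = 1000
    # motifs
    motif_flank: int = 2000
    # GSEA
    gsea_weight: float = 1.0
    gsea_n_perm: int = 1000
    # synthetic study sizes
    study: StudyParams = field(default_factory=StudyParams)

    def validate(self) -> None:
        def check(cond: bool, name: str, why: str) -> None:
            if not cond:
                raise ValueError(f"invalid config field {name!r}: {why}")

        check(0 < self.sharp_p < 1, "sharp_p", "must lie in (0, 1)")
        check(self.broad_window > 0, "broad_window", "must be positive")
        check(self.broad_gap >= 0, "broad_gap", "must be non-negative")
        check(0 < self.broad_fdr < 1, "broad_fdr", "must lie in (0, 1)")
        check(self.diff_fold >= 1, "diff_fold", "must be >= 1")
        check(0 < self.diff_p < 1, "diff_p", "must lie in (0, 1)")
        check(self.expr_fold > 1, "expr_fold", "must be > 1")
        check(0 < self.detection_alpha < 1, "detection_alpha", "must lie in (0, 1)")
        check(self.expr_floor >= 0, "expr_floor", "must be non-negative")
        check(self.distal_min >= 0, "distal_min", "must be non-negative")
        check(self.min_enhancer_span >= 0, "min_enhancer_span", "must be non-negative")
        check(self.motif_flank > 0, "motif_flank", "must be positive")
        check(self.gsea_n_perm >= 100, "gsea_n_perm", "must be >= 100")
        check(self.study.n_per_state >= 0, "study.n_per_state", "must be >= 0")
        check(self.study.n_reps >= 2, "study.n_reps", "must be >= 2")
        check(self.study.depth > 0, "study.depth", "must be positive")
        check(
            0 <= self.study.censor_fraction < 1,
            "study.censor_fraction",
            "must lie in [0, 1)",
        )
        check(self.study.hazard_ratio > 0, "study.hazard_ratio", "must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        study_raw = raw.pop("study", {})
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"invalid config field {sorted(unknown)[0]!r}: unknown")
        study_known = {f.name for f in fields(StudyParams)}
        unknown = set(study_raw) - study_known
        if unknown:
            raise ValueError(f"invalid config field study.{sorted(unknown)[0]!r}: unknown")
        cfg = cls(**{k: v for k, v in raw.items() if k != "study"})
        cfg.study = StudyParams(**study_raw)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        return d
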