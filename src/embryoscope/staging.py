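"""Embryo staging helpers: developmental phases for stages 6-19."""

from __future__ import annotations

from .errors import ConfigurationError

STAGE_MIN = 6
STAGE_MAX = 19

#: phase -> inclusive stage range
PHASE_STAGES = {
    "blastulation": range(6, 9),
    "organogenesis": range(9, 14),
    "activation": range(14, 17),
    "growth": range(17, 20),
}

PHASE_ORDER = tuple(PHASE_STAGES)


def phase_for_stage(stage: int) -> str:
    """Return the developmental phase a stage belongs to."""
    stage = int(stage)
    for phase, stages in PHASE_STAGES.items():
        if stage in stages:
            return phase
    raise ConfigurationError(
        f"stage {stage} outside supported range {STAGE_MIN}..{STAGE_MAX}"
    )


def validate_stage(stage: int) -> int:
    stage = int(stage)
    if not STAGE_MIN <= stage <= STAGE_MAX:
        raise ConfigurationError(
            f"stage {stage} outside supported range {STAGE_MIN}..{STAGE_MAX}"
        )
    return stage
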