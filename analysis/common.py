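"""Shared design of the synthetic dose-escalation study used by the drivers.

Four dose groups spanning the i.v. escalation range, each with a chosen
mean dystrophin-positive perimeter fraction and transcript mix.  These
per-dose settings are study design inputs to the generators, not fitted
quantities; the pipeline is then asked to recover them blind.
"""

from pathlib import Path

RESULTS = Path(__file__).resolve().parent.parent / "results"

# dose label -> (mean perimeter fraction, beta concentration,
#                RT-PCR area ratio Dup2:WT:D2, eccentric retention/step)
DOSE_DESIGN = {
    "vehicle": (0.05, 8.0, (0.90, 0.07, 0.03), 0.82),
    "low": (0.25, 6.0, (0.60, 0.25, 0.15), 0.88),
    "mid": (0.55, 6.0, (0.35, 0.40, 0.25), 0.94),
    "high": (0.85, 8.0, (0.15, 0.45, 0.40), 0.985),
}
SECTIONS_PER_DOSE = 3
MICE_PER_DOSE = 6
BASE_SEED = 20_260_101


def dose_seed(dose: str, index: int) -> int:
    return (BASE_SEED + 1009 * list(DOSE_DESIGN).index(dose) + index) % (2 ** 31)
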