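"""Survival and viability arithmetic.

Two small computations used when quantifying antibiotic tolerance from
plate counts and live/dead microscopy: percent survival of colony-forming
units (CFU) across a treatment, and the viable-but-not-culturable (VBNC)
excess of live-stained cells over culturable ones. Inputs are expected to
be replicate-averaged densities (per ml); both quantities are invariant to
rescaling the inputs by a common factor.
"""

from __future__ import annotations

import logging

from .errors import UsageError

logger = logging.getLogger(__name__)


def percent_survival(cfu_before: float, cfu_after: float) -> float:
    """Percent of colony-forming units surviving treatment.

    ``100 * cfu_after / cfu_before``; ``cfu_before`` must be positive.
    """
    if cfu_before <= 0:
        raise UsageError("cfu_before must be positive")
    if cfu_after < 0:
        raise UsageError("cfu_after must be non-negative")
    return 100.0 * cfu_after / cfu_before


def vbnc_fold(live_per_ml: float, cfu_per_ml: float) -> tuple[float, float]:
    """VBNC density and its fold over culturable cells.

    VBNC cells are estimated as live-stained cells/ml minus CFU/ml; the
    fold is that excess divided by CFU/ml. A live count below the CFU count
    reflects counting noise and clips VBNC to zero with a warning rather
    than erroring.
    """
    if cfu_per_ml <= 0:
        raise UsageError("cfu_per_ml must be positive")
    if live_per_ml < 0:
        raise UsageError("live_per_ml must be non-negative")
    vbnc = live_per_ml - cfu_per_ml
    if vbnc < 0:
        logger.warning(
            "live count %.3g below CFU count %.3g; clipping VBNC to 0",
            live_per_ml,
            cfu_per_ml,
        )
        vbnc = 0.0
    return vbnc, vbnc / cfu_per_ml
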