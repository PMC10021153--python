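"""Published reference values for the LASI 2017-18 multimorbid cohort.

Small constants used for bookkeeping cross-checks that need no
microdata: the gender stratum sizes of the multimorbid sample and the
per-disease degree sequences and edge counts of the reported gender-
specific disease networks.  The degree sequences let the handshake
lemma (sum of degrees = 2E) reconstruct each network's edge count.

These are *reference inputs*, never substitutes for computation on a
cohort: nothing in the analysis pipeline reads them.
"""

from __future__ import annotations

from .codebook import CODES

__all__ = [
    "STRATUM_SIZES",
    "TOTAL_MULTIMORBID",
    "REPORTED_DEGREES",
    "REPORTED_EDGE_COUNTS",
]

#: Multimorbid individuals per gender stratum (LASI wave 1, 2017-18).
STRATUM_SIZES: dict[str, int] = {"women": 10_606, "men": 7_912}

#: Reported multimorbid total, which the strata must sum to.
TOTAL_MULTIMORBID: int = 18_518

#: Reported node degrees of the gender-specific disease networks,
#: codebook order (AS ... UI).
REPORTED_DEGREES: dict[str, tuple[int, ...]] = {
    "women": (2, 3, 6, 7, 9, 7, 4, 2, 4, 5, 3, 4, 1, 5, 5, 3),
    "men":   (2, 4, 6, 2, 3, 5, 2, 1, 5, 3, 2, 3, 0, 2, 5, 5),
}

#: Reported edge counts after the inclusion rule (p < 0.05, OR >= 1.2).
REPORTED_EDGE_COUNTS: dict[str, int] = {"women": 35, "men": 25}

assert all(len(v) == len(CODES) for v in REPORTED_DEGREES.values())
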