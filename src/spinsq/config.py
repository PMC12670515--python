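"""Runtime configuration and instrumentation counters.

Settings are deliberately module-global: the algebra is single-threaded and
the CLI maps flags / an optional ``key=value`` config file straight onto
these fields.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass
class Settings:
    #: Cap on the number of summation-index permutations examined while
    #: canonicalizing a single term.  Above the cap a deterministic greedy
    #: fallback is used and the term is flagged non-canonical via a warning.
    permutation_cap: int = math.factorial(10)
    #: Below this candidate count the search enumerates all permutations
    #: within each orbital-space group (true lexicographic minimum);
    #: above it, indices are first partitioned into structural
    #: interchangeability cells and only within-cell permutations are
    #: enumerated (deterministic and relabelling-invariant, which is all
    #: that term fusion requires).
    exact_permutation_cap: int = 24
    #: Reject floating-point scalars (round-off breaks exact cancellation).
    scalar_type_guard: bool = True
    #: Rendering dialect: "unicode" or "ascii".
    render_dialect: str = "unicode"
    #: Memoize term-level commutators (BCH re-derives many subcommutators).
    memoize_commutators: bool = True
    #: Abort derivations whose intermediate expressions exceed this size.
    term_limit: int = 10**6


@dataclass
class Stats:
    """Instrumented counters (reset with :func:`reset_stats`)."""

    kernel_invocations: int = 0
    permutations_enumerated: int = 0
    permutation_cap_hits: int = 0


settings = Settings()
stats = Stats()


def reset_stats() -> None:
    stats.kernel_invocations = 0
    stats.permutations_enumerated = 0
    stats.permutation_cap_hits = 0


def load_config_file(path: str) -> None:
    """Apply ``key=value`` pairs from a small plain-text config file."""
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key = key.strip()
            value = value.strip()
            if not hasattr(settings, key):
                raise KeyError(f"unknown config key {key!r}")
            current = getattr(settings, key)
            if isinstance(current, bool):
                setattr(settings, key, value.lower() in ("1", "true", "yes"))
            elif isinstance(current, int):
                setattr(settings, key, int(value))
            else:
                setattr(settings, key, value)
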