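"""Default English stop-word list plus hooks for a domain-specific list.

Word-frequency statistics over phylogenetics articles are dominated by
function words unless they are excluded; an additional, configurable domain
list lets users drop field-generic words (e.g. "study", "results") that are
uninformative for timetree triage without being English stop words.
"""

from __future__ import annotations

from typing import Iterable

# Compact general-English list; intentionally conservative so that domain
# vocabulary (e.g. "time", "tree") is never silently removed.
DEFAULT_STOPWORDS = frozenset(
    """
    a about above after again against all am an and any are as at be because
    been before being below between both but by can cannot could did do does
    doing down during each few for from further had has have having he her
    here hers herself him himself his how i if in into is it its itself just
    me more most my myself no nor not now of off on once only or other our
    ours ourselves out over own same she should so some such than that the
    their theirs them themselves then there these they this those through to
    too under until up very was we were what when where which while who whom
    why will with would you your yours yourself yourselves
    et al fig figs figure figures table tables
    """.split()
)


def stopword_set(extra: Iterable[str] | None = None) -> frozenset[str]:
    """The default stop-word set, optionally extended by a domain list."""
    if extra is None:
        return DEFAULT_STOPWORDS
    return DEFAULT_STOPWORDS | frozenset(w.lower() for w in extra)
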