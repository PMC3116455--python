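"""Default English stop-word list.

A standard general-English function-word list (the classic 127-word list
used widely in IR toolkits).  Users may supply their own list; experiment
logs record a hash of whichever list was active.
"""

from __future__ import annotations

import hashlib

DEFAULT_STOP_WORDS: frozenset[str] = frozenset(
    """
    i me my myself we our ours ourselves you your yours yourself yourselves
    he him his himself she her hers herself it its itself they them their
    theirs themselves what which who whom this that these those am is are
    was were be been being have has had having do does did doing a an the
    and but if or because as until while of at by for with about against
    between into through during before after above below to from up down in
    out on off over under again further then once here there when where why
    how all any both each few more most other some such no nor not only own
    same so than too very s t can will just don should now
    """.split()
)


def stop_list_hash(stop_words: frozenset[str] | set[str]) -> str:
    """Deterministic hash of a stop-word set, for experiment provenance."""
    joined = "\n".join(sorted(stop_words))
    return hashlib.sha256(joined.encode("utf-8")).hexdigest()[:16]


def load_stop_words(path: str) -> frozenset[str]:
    """Read a user-supplied stop list: one word per line, lowercased."""
    with open(path, encoding="utf-8") as fh:
        return frozenset(w.strip().lower() for w in fh if w.strip())
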