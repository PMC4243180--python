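"""Default English stop-word list.

The classic 33-word analyzer stop list used by mainstream full-text
search libraries for English.  Production biomedical search engines
often extend it; any list can be substituted via the ``stoplist``
arguments or a one-word-per-line text file on the CLI.
"""

DEFAULT_STOPWORDS = frozenset(
    {
        "a", "an", "and", "are", "as", "at", "be", "but", "by", "for",
        "if", "in", "into", "is", "it", "no", "not", "of", "on", "or",
        "such", "that", "the", "their", "then", "there", "these", "they",
        "this", "to", "was", "will", "with",
    }
)


def load_stoplist(path) -> frozenset:
    """Read a stop list from a text file, one word per line.

    Blank lines and lines starting with ``#`` are ignored; words are
    lowercased.
    """
    words = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            word = line.strip().lower()
            if word and not word.startswith("#"):
                words.add(word)
    return frozenset(words)
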