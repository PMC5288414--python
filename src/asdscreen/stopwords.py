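"""Default English stop-word list (174 words).

A standard list of high-frequency English function words — articles,
pronouns, auxiliaries, conjunctions and common prepositions — removed before
building lexical features.  Any iterable of strings may be passed to
:func:`asdscreen.text.tokenize` to override it.
"""

DEFAULT_STOPWORDS = frozenset("""
a about above after again against all also although always am among an and
another any anybody anyone anything are aren around as at away be became
because become came come either else even ever every everyone everything get
go goes going gone got however
been before being below between both but by can cannot could couldn did didn
do does doesn doing don down during each few for from further had hadn has
hasn have haven having he her here hers herself him himself his how i if in
into is isn it its itself just me might more most must mustn my myself no nor
not now of off on once only or other our ours ourselves out over own same
shall shan she should shouldn so some such than that the their theirs them
themselves then there these they this those through to too under until up very
was wasn we were weren what when where which while who whom why will with won
would wouldn you your yours yourself yourselves
""".split())
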