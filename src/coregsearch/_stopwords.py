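"""Fixed English stopword list used by the metadata tokenizer.

A small, frozen list is shipped with the package so that tokenization is
reproducible across installations; coverage is deliberately traded for
stability.
"""

STOPWORDS: frozenset[str] = frozenset(
    """
    the and for are but not you all any can had her was one our out day get
    has him his how man new now old see two way who boy did its let put say
    she too use that with this from they have been were said each which their
    will other about many then them these some would like into time more only
    over such your also after most made before here through when where while
    both between under during against further than once very just because
    until being again same above below down off few how why what does doing
    own those there himself herself itself themselves ourselves yourselves
    myself yourself whom having each should could might must shall may per via
    upon among amongst within without across toward towards onto
    """.split()
)
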