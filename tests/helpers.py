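"""Shared helpers for the test suite."""

from pacdetect.io import BeatAnnotation, simplify_label


def make_annotations(samples, symbols=None):
    samples = list(samples)
    symbols = symbols or ["N"] * len(samples)
    return [
        BeatAnnotation(int(s), sym, simplify_label(sym))
        for s, sym in zip(samples, symbols)
    ]
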