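"""Bundled observer-study score tables.

Per-observer mean preference scores from a paired-comparison reading study
of three processing methods ("sigmoid" coefficient mapping alone, "udwt"
denoising alone, and the combined pipeline), graded by five radiological
technologists on the -2..+2 scale.  Positive scores favour the left method
of each pair.  Useful as worked examples for
:func:`waveclear.quality_metrics.aggregate_preference_scores`.
"""
from .quality_metrics import ScoreTable

MAMMOGRAM_PREFERENCE_SCORES = ScoreTable(
    combinations=[
        ("sigmoid", "udwt"),
        ("sigmoid", "combined"),
        ("udwt", "combined"),
    ],
    scores=[
        [-1.1, -0.87, 0.0, -1.2, -1.2],
        [-1.57, -1.4, -1.67, -1.47, -1.6],
        [-1.33, -1.27, -1.47, -1.3, -1.5],
    ],
)

CHEST_PREFERENCE_SCORES = ScoreTable(
    combinations=[
        ("sigmoid", "udwt"),
        ("sigmoid", "combined"),
        ("udwt", "combined"),
    ],
    scores=[
        [-1.0, -0.4, -0.1, -0.95, -1.25],
        [-1.7, -1.4, -1.35, -1.4, -1.65],
        [-1.5, -1.35, -1.5, -1.4, -1.55],
    ],
)
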