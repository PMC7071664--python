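"""Lignocellulose classification with activity override and fallback.

Watchlist families can host both lignocellulolytic and other-substrate
enzymes; an explicit activity prediction decides, and calls without one
take the family's most common activity.
"""

from holocaz import ActivityPrediction, classify_calls, load_class_map, summarize_classes
from holocaz.consensus import CazymeCall
from holocaz.model import Tool

ALL = frozenset(Tool)
calls = [
    CazymeCall("orf_1", "GH5", ALL, 1, "demo"),    # predicted cellulase
    CazymeCall("orf_2", "GH5", ALL, 1, "demo"),    # predicted chitinase
    CazymeCall("orf_3", "AA1", ALL, 1, "demo"),    # no prediction -> laccase
    CazymeCall("orf_4", "GH13", ALL, 1, "demo"),   # not on the watchlist
]
activities = [
    ActivityPrediction("orf_1", "GH5", "cellulase"),
    ActivityPrediction("orf_2", "GH5", "chitinase"),
]

class_map = load_class_map()
annotated = classify_calls(calls, activities, class_map)
for a in annotated:
    print(f"{a.call.orf_id}  {a.call.family:5s}  {a.status:15s} "
          f"role={a.role or '-':25s} source={a.activity_source or '-'}")

summary = summarize_classes(annotated)
print(f"\nwatchlist modules: {summary.n_watchlist_modules}, "
      f"predicted: {summary.n_predicted_modules}, "
      f"lignocellulolytic among predicted: "
      f"{summary.pct_ligno_predicted:.1f}%")
print("orf_2 shows why predictions matter: a GH5 acting on chitin is not a")
print("lignocellulose degrader even though GH5 is a classic cellulase family.")
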