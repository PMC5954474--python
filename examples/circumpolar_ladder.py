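"""Circumpolar zoobenthic production, scaled rung by rung.

Starts from a mean organic production of 3 g C m-2 yr-1 (numerically
equal to 3 t C km-2 yr-1), adds carbonate carbon, doubles for the
under-sampled shallows, multiplies by the continental-shelf area, and
then applies the sea-ice-loss, ice-shelf-loss and sub-Antarctic
corrections.  Both the rounded (as-reported) and exact branches are
shown; the ladder is replayable, so each printed rung can be recomputed
from its stored inputs.
"""

from bergcarbon import full_ladder, load_params

params = load_params()
reported = full_ladder(params, reported=True)
raw = full_ladder(params, reported=False)

print(f"{'rung':<50s} {'reported':>10s} {'raw':>10s}")
for (label, _, _, rep), (_, _, _, rw) in zip(reported.rungs, raw.rungs):
    print(f"{label:<50s} {rep:>10g} {rw:>10.4g}")

assert reported.replay() == reported.final_total
print()
print(f"circumpolar zoobenthic carbon production: about "
      f"{reported.final_total:g} Mt C yr-1")
print("(the last three rungs are in Mt C yr-1; the first two are "
      "t C km-2 yr-1)")
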