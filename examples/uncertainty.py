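"""Monte-Carlo envelopes over the published parameter ranges.

Samples the parameters that carry published ranges (growth 2-3x,
fertilization 5-10x, standing stock 8-16 t C km-2, ...) uniformly and
pushes the draws through the raw budget arithmetic.  Also prints the
exact corner bounds: because the budget is monotone in every parameter,
the extreme outputs sit at corners of the parameter box.
"""

from bergcarbon import load_params, propagate, sample_params

params = load_params()
draws = sample_params(params, n=20_000, seed=0, distribution="uniform")
envelopes = propagate("budget", draws, params)

for name, env in envelopes.items():
    print(f"{name}:")
    print(f"  median          {env.median:>14,.0f} t C yr-1")
    print(f"  central 95%     [{env.q025:,.0f}, {env.q975:,.0f}]")
    print(f"  sampled range   [{env.vmin:,.0f}, {env.vmax:,.0f}]")
    print(f"  exact bounds    [{env.corner_low:,.0f}, {env.corner_high:,.0f}]")

print()
print("The cost envelope spans exactly [20 000, 40 000] t C yr-1 — the "
      "scour cost is linear in the 8-16 t C km-2 standing-stock range "
      "and nothing else in it varies.")
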