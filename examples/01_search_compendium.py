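"""Build a small synthetic compendium and search it with a module query.

Twenty null datasets plus one dataset carrying a planted coregulated module
are preprocessed and ranked against the module's gene signature. The score is
the percentage of each dataset's variance explained by the query direction:
the planted dataset should lead by an order of magnitude.
"""

from coregsearch import PlantedSpec, make_compendium, module_signature, rank_compendium

spec = PlantedSpec(n_genes=500, m_samples=20, module_size=30, effect_a=2.0, seed=42)
store = make_compendium(n_null=20, planted_specs=[spec], seed=0)
out = rank_compendium(store, module_signature(spec))

print(f"{'rank':>4}  {'dataset':<10} {'k':>3}  {'% variance explained':>20}")
for row in out.results[:5]:
    print(f"{row.rank:>4}  {row.dataset_id:<10} {row.k:>3}  {row.score:>20.3f}")
print(
    "\nThe planted dataset explains far more variance along the query direction\n"
    "than any null dataset; null scores sit near 100/n_genes = 0.2%."
)
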