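"""The oxygen dose-response curve for Eastern Baltic cod egg survival.

Survival before hatch rises sigmoidally with ambient oxygen:
y = 100 * (1 - exp(-0.71 x))^11.63 (x in ml/l).  The three reference values
bracket the habitat quality scale: eggs are essentially lost at 2 ml/l,
half are lost at 4 ml/l, and mortality is below 10% at 7 ml/l.
"""

from inflowcast import egg_survival, half_survival_oxygen

for oxygen in (2.0, 4.0, 7.0):
    y = egg_survival(oxygen)
    print(f"oxygen {oxygen:.0f} ml/l -> survival {y:5.1f}%  (mortality {100 - y:5.1f}%)")

print(f"half-survival oxygen content: {half_survival_oxygen():.2f} ml/l")
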