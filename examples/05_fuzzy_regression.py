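"""Fit the possibilistic fuzzy regression and render its three equations.

The minimum-spread linear program gives each coefficient a triangular
fuzzy number; the central equation uses the centers, the lower/upper
boundary equations the support edges.  At h = 0 the band between the
boundary equations contains every training observation.
"""

from possireg import (
    GeneratorConfig,
    encode_dummies,
    fit_possibilistic,
    format_model_equations,
    generate,
    predict_fuzzy,
)

table = generate(GeneratorConfig(n=30, seed=6))
design = encode_dummies(table)

model = fit_possibilistic(design, h_level=0.0, mode="symmetric")
print(model.to_frame().round(5).to_string(index=False))
central, lower, upper = format_model_equations(model)
print(f"\nCentral tendency: {central}\nLower boundary:   {lower}\nUpper boundary:   {upper}")
print(f"total weighted spread (LP objective): {model.objective_value:.2f}")

p = predict_fuzzy(model, {"Waist": 95.0, "HDL": 50.0, "Border": 0.0, "Hyper": 1.0})
print(f"\nfuzzy prediction at waist 95 / HDL 50 / hypertensive: "
      f"{p.center:.1f} mg/dL, support [{p.lower:.1f}, {p.upper:.1f}]")
# The support interval is the possibilistic band: the model asserts the
# observation is possible anywhere inside it, with full possibility at the
# center.
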