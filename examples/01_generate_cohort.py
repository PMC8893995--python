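"""Generate a synthetic 14-patient lipid cohort and inspect it.

Draws waist circumference and HDL from Gaussians, a three-level
blood-pressure code from a categorical distribution, and triglycerides
as a linear function of the encoded covariates plus noise.
"""

from possireg import GeneratorConfig, generate

table = generate(GeneratorConfig(n=14, seed=1))
print(table.data.round(2).to_string())
print(
    f"\n{len(table)} patients; blood-pressure codes "
    f"{sorted(table.data['BloodPressure'].unique())} "
    "(0 normal, 1 borderline, 2 high)."
)
# Each row is one patient record: triglycerides (mg/dL) responds to waist
# (cm), HDL (mg/dL) and blood-pressure status with known true coefficients.
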