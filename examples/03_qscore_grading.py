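"""Grade fruit with the Q score: z-score distances to per-grade references.

Ten hand-graded reference fruit per grade define each grade's mean and
spread for color, size and weight; a new fruit gets
Q = (e^-dR + e^-dW + e^-dS)/3 against every grade and is assigned the
argmax.  Q = 1 means a perfect match to the grade's reference means.
"""

from fruitgrade import ColorSampleConfig, assign_grade, extract_features
from fruitgrade.grading import fit_references
from fruitgrade.synthetic import load_preset, sample_grade_population

grades, template = load_preset("peach")

training = []
for params in grades:
    for s in sample_grade_population(params, template, 10, rng_seed=100 + params.grade_index):
        fv = extract_features(s.image, s.mask, s.weight_g, ColorSampleConfig(rng_seed=0))
        training.append((fv, s.true_grade))

refs = fit_references(training, n_reference=10)

probe = sample_grade_population(grades[2], template, 1, rng_seed=999)[0]  # a grade-3 peach
fv = extract_features(probe.image, probe.mask, probe.weight_g, ColorSampleConfig(rng_seed=1))
result = assign_grade(fv, refs)

print(f"true grade: {probe.true_grade}, assigned grade: {result.assigned_grade}")
for g in (1, 2, 3, 4):
    dR, dS, dW = result.distances[g]
    print(f"  grade {g}: dR={dR:6.2f} dS={dS:6.2f} dW={dW:6.2f}  Q={result.q[g]:.4f}")
# the true grade has the smallest distances, hence the largest Q
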