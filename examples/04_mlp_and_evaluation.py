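"""Train the back-propagation MLP grader and evaluate it with one-vs-rest
sensitivity/specificity and micro-averaged accuracy."""

from fruitgrade import ColorSampleConfig, MLPConfig, extract_features
from fruitgrade.classify import (
    build_vectors,
    confusion_matrix,
    feature_matrix,
    predict_mlp,
    report_text,
    train_mlp,
)
from fruitgrade.synthetic import load_preset, sample_grade_population

grades, template = load_preset("tomato")

features, labels = [], []
for params in grades:
    for i, s in enumerate(sample_grade_population(params, template, 30, rng_seed=params.grade_index)):
        fv = extract_features(s.image, s.mask, s.weight_g, ColorSampleConfig(rng_seed=i))
        features.append(fv)
        labels.append(s.true_grade)

train_n = 15  # per grade: first 15 train, last 15 test
train_idx = [i for i in range(len(labels)) if i % 30 < train_n]
test_idx = [i for i in range(len(labels)) if i % 30 >= train_n]

X_train, T_train, scaler = build_vectors([features[i] for i in train_idx], [labels[i] for i in train_idx])
model = train_mlp(X_train, T_train, MLPConfig(hidden_sizes=(10,), epochs=500, rng_seed=0))

X_test = scaler.transform(feature_matrix([features[i] for i in test_idx]))
pred = predict_mlp(model, X_test)
cm = confusion_matrix([labels[i] for i in test_idx], pred)
print(report_text(cm))
# sensitivity: share of each true grade recovered; specificity: share of
# other-grade fruit correctly kept out; accuracy: trace/total
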