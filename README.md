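# lbptop

Isotropic **LBP-TOP** texture features, SVM-weight feature selection and
cross-validated classification for volumetric brain images.

Structural brain differences between clinical groups — for example between
children with ADHD and typically developing controls — show up as subtle
morphological texture changes in registered T1 images or tissue probability
maps, rather than as simple intensity shifts. This package quantifies such
texture with local binary patterns computed on the three orthogonal planes
of a 3D volume, turns the per-region code histograms into subject feature
vectors, and evaluates how well a linear SVM (or 1-NN baseline) separates
two groups under a rigorously nested cross-validation protocol, with
permutation and McNemar tests for significance. A seeded synthetic-phantom
generator makes the whole pipeline runnable and testable without any
imaging data.

## Method

For a voxel with value v<sub>c</sub>, the LBP code thresholds P neighbors
sampled on a circle of radius R (in mm, converted to voxels) against the
center:

```
LBP_{P,R} = Σ_{p=0}^{P-1} s(v_p − v_c) · 2^p,    s(x) = 1 if x ≥ 0 else 0
```

Neighbor p sits at angle 2πp/P from the +first-axis direction
(counter-clockwise), bilinearly interpolated when off-grid. **LBP-TOP**
applies this on the xy, xz and yz planes through every voxel with the same
radius and concatenates the three plane histograms. Uniform-pattern mapping
keeps a separate bin for each code with at most two circular bitwise
transitions (U ≤ 2) and pools all others into one bin — 59 bins for P = 8,
so a whole-brain mask yields 3 × 59 = 177 features, a 116-region AAL-style
atlas 20 532, and a 190-region CC200-style atlas 33 630.

Feature groups (e.g. different radii or parcellations) are merged by
iterative selection: append a group, grid-search the SVM penalty C by
internal 10-fold CV, fit, rank features by |w|, keep the better half
(whole-brain-scale groups are exempt from the drop). Evaluation is outer
10-fold cross-validation with selection and grid search nested inside each
training split; significance comes from the permutation test
p = (#{randomized error ≤ observed} + 1)/(k + 1) with k = 100, and paired
classifiers are compared with McNemar's test on their discordant
predictions. Pairwise Pearson correlations between region timecourses
(6 670 for 116 regions) provide a functional-connectivity reference
feature set.

## Worked example

```python
import lbptop as lt

spec = lt.PhantomSpec(shape=(20, 20, 20), class_effect=2.0, seed=0)
volumes, y, atlas, labels = lt.generate_cohort(spec, n_per_class=15)

extractor = lt.LBPTOPExtractor(atlas=atlas, radii_mm=(1.0, 2.0)).fit()
X = extractor.transform(volumes)

plan = lt.make_cv_plan(range(len(y)), n_folds=10, seed=0)
res = lt.cross_validate(X, y, plan, classifier="svm")
perm = lt.permutation_test(
    lambda X_, y_: lt.cross_validate(X_, y_, plan, "svm", reuse_C=1.0),
    X, y, k=100, seed=0)
```

prints (via the obvious `print` statements):

```
feature matrix: 30 subjects x 354 features (2 radius groups of 177)
10-fold linear-SVM accuracy: 1.000
confusion matrix:
[[15  0]
 [ 0 15]]
chosen C per fold: [0.03125, 0.125, 0.125, 0.125, 0.125, 0.0625, 0.0625, 0.0625, 0.0625, 0.0625]
permutation p-value (k=100): 0.0099
```

The two classes differ only in the *smoothing scale* of their texture
(class 1 smoother than class 0), a difference invisible to mean intensity
but fully captured by the LBP code distribution: held-out accuracy is
perfect and the permutation p-value reaches its minimum attainable value
1/101 ≈ 0.0099.

The same workflow is available from the shell:

```bash
lbptop simulate --out cohort --n-per-class 15 --class-effect 2.0 --seed 0
lbptop extract  --data cohort --out features --radii 1,2
lbptop evaluate --features features/features_R1mm.tsv --labels cohort/labels.tsv \
                --classifier svm --pred-out pred_svm.tsv
lbptop permtest --features features/features_R1mm.tsv --labels cohort/labels.tsv --k 100
lbptop mcnemar  pred_svm.tsv pred_knn.tsv
```

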