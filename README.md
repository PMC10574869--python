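# flatfoot

Automated severity grading of pes planus (flat foot) from lateral
weight-bearing foot radiographs.

Flat foot is graded from standing X-rays by drawing lines between
anatomical landmarks and measuring the angles they form. Doing this by
hand is slow and inter-observer variability is real; `flatfoot`
automates the whole chain for clinical-imaging researchers and
medical-image-analysis engineers:

1. **Landmark localization** — nine points of interest (PoIs) on the
   first metatarsal, fifth metatarsal, calcaneus, talus and sesamoid are
   located by sliding 100×100-px templates over the image with the
   normalized squared-difference score
   `R = Σ(T−I)² / √(ΣT²·ΣI²)` (0 = perfect; candidates need similarity
   `1−R ≥ 0.90`), then re-ranked by a random-forest patch classifier
   (100 trees, random state 42); the winning patch center is the
   landmark.
2. **Angle measurement** — three clinical angles from the landmarks:
   * *Calcaneal Inclination Angle* (CIA): calcaneal inferior line vs.
     the sesamoid base line, via `tan θ = |m₂−m₁| / |1+m₁m₂|`;
   * *Meary's Angle* (MA): talar axis vs. first-metatarsal axis, same
     formula;
   * *Arch Angle* (AA): calcaneal vs. fifth-metatarsal inferior lines,
     as a signed directed angle so a collapsed arch reads ≥ 180°.
3. **Grading and vote** — each angle votes normal / mild / moderate
   against published intervals (CIA 20–30 normal, AA 150–165 normal,
   MA < 4 normal, …); the majority wins, with three-way ties broken by
   angle reliability CIA > MA > AA.

Because annotated clinical radiographs cannot be redistributed, the
package includes a **phantom generator**: synthetic 1024×1024
radiographs of five stylized bones rendered at *requested* angles, with
exact ground-truth landmarks. Everything — matching, selection,
measurement, grading — is validated end to end on phantoms. See
`docs/methods.md` for the model, conventions and limitations.

## Worked example

```python
from flatfoot import FlatFootDiagnoser, PhantomSpec, generate_phantom, sample_dataset

# a small annotated training set (phantoms stand in for annotated scans)
train, manifest = sample_dataset({"normal": 2, "mild": 2, "moderate": 2}, seed=11)
model = FlatFootDiagnoser().fit(train)   # crops templates + trains the forest

img, truth = generate_phantom(PhantomSpec(target_class="mild", seed=99))
bundle = model.diagnose(img)

a, d = bundle["angles"], bundle["diagnosis"]
print(f"ground truth: CIA={truth.angles.cia_deg:.2f}  AA={truth.angles.aa_deg:.2f}  "
      f"MA={truth.angles.ma_deg:.2f}  class={truth.class_label}")
print(f"measured:     CIA={a.cia_deg:.2f}  AA={a.aa_deg:.2f}  MA={a.ma_deg:.2f}")
print(f"votes: {d.votes}")
print(f"counts: {d.counts}")
print(f"final: {d.final}")
```

Output:

```
ground truth: CIA=15.04  AA=173.22  MA=9.59  class=mild
measured:     CIA=15.40  AA=173.12  MA=9.50
votes: {'CIA': 'mild', 'AA': 'mild', 'MA': 'mild'}
counts: {'normal': 0, 'mild': 3, 'moderate': 0}
final: mild
```

The three measured angles sit within a few degrees of the construction
values (the landmarks were found by matching + classification, not read
from ground truth), each angle independently votes *mild*, and the
unanimous vote is the final grade. `FlatFootDiagnoser` is a
scikit-learn-style estimator (`get_params` / `set_params` /
`fit` / `predict`), so it composes with sklearn model selection;
`bundle` also carries the nine landmarks for auditing.

### Command line

The same stages are available as subcommands:

```sh
flatfoot simulate --normal 3 --mild 3 --moderate 2 --seed 0 --out-dir data/
flatfoot templates --dataset data/ --out-dir tlib/
flatfoot train --dataset data/ --out model.joblib
flatfoot diagnose data/images/<id>.png --templates tlib/ --model model.joblib
flatfoot evaluate --dataset data/ --templates tlib/ --model model.joblib --out-dir report/
flatfoot sweep --dataset data/ --templates tlib/ --out sweep.csv
```

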