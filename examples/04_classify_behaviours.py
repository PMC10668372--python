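"""Train the balanced forest + HMM and classify a held-out recording.

Training epochs come from synthetic participants with ground-truth 3-class
labels (standing in for camera-annotated validation data); the trained
model then labels an unseen week, and the confusion matrix compares
against truth, including the LIPA/MVPA split at 100 mg.
"""

import numpy as np

import wristtime as wt
from wristtime import classify

cfg = wt.PipelineConfig(sample_rate_hz=25.0, seed=1)

train_set = wt.pipeline.build_training_set(cfg, days=1)
model = classify.train(train_set, n_trees=100, seed=5)
print(f"trained on {len(train_set.labels)} epochs; "
      f"OOB accuracy {model.forest.oob_accuracy(train_set.labels):.3f}")
print("HMM transition matrix (sleep/sedentary/non-sedentary):")
print(model.hmm.transition.round(3))

schedule = wt.synth.make_schedule("ckb_like", days=2, seed=99)
device = wt.synth.DeviceModel(sample_rate=25.0, device_id="held-out")
recording, truth = wt.synth.synthesize_recording(schedule, device, seed=100)
donor = wt.rawproc.CalibrationModel(offset=np.zeros(3), gain=np.ones(3),
                                    source="self", sphere_coverage_ok=True,
                                    device_id="held-out")
epochs, _, _ = wt.process_recording(recording, cfg, donor=donor)
sequence = classify.predict(epochs, model)

n = min(epochs.n_epochs, len(truth.epoch_label))
acc = classify.accuracy(classify.BehaviourSequence(sequence.labels[:n]),
                        truth.epoch_label[:n])
print(f"\nheld-out 4-class epoch accuracy: {acc:.3f}")
print(classify.confusion_matrix(
    classify.BehaviourSequence(sequence.labels[:n]), truth.epoch_label[:n]))
# Rows are truth, columns predictions; the diagonal dominates because the
# HMM smooths away isolated forest errors inside long behaviour runs.
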