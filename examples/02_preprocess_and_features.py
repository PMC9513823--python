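"""Preprocess one synthetic recording and extract the 1333-entry feature
vector.

Shows the full chain for a single subject: resting-segment extraction
(minute 1 to minute 4), zero-phase 1-100 Hz filtering, average
re-referencing, ICA artifact rejection with the oracle labeler, and the
feature census (absolute/relative band power, coherence, spectral entropy,
phase-amplitude coupling, demographics)."""

from qeegml import default_profiles, generate_subject, inject_artifacts
from qeegml.features import extract_features
from qeegml.preprocess import OracleLabeler, extract_resting_segment, ica_artifact_removal, raw_variant
from qeegml.synthetic import artifact_signal_from_log

profile = default_profiles()["TBI"]
rec = generate_subject(profile, duration_s=240, fs=250, seed=7, subject_id="demo")
rec, events = inject_artifacts(rec, profile.artifact_rates, seed=8)
print(f"generated {rec.subject_id}: {rec.n_channels} channels, "
      f"{rec.duration:.0f} s at {rec.fs:.0f} Hz, {len(events)} artifact events")

segment = extract_resting_segment(rec)
raw = raw_variant(segment)
print(f"raw variant: {raw.duration:.0f} s analysis segment, "
      f"channel-mean {abs(raw.data.mean(axis=0)).max():.2e} uV (average-referenced)")

i0 = int(60 * rec.fs)
artifacts = {"eye": artifact_signal_from_log(events, rec.n_samples, rec.fs,
                                             types=("eye",))[:, i0:i0 + raw.n_samples]}
clean, report = ica_artifact_removal(raw, OracleLabeler(artifacts), seed=0)
print(f"ICA: {report.n_components} components, kept {report.n_kept} "
      f"(rejected: {[l for l in report.labels if l != 'brain']})")

features = extract_features(clean, include_demo=True)
print(f"\nfeature vector length: {len(features)} (1330 EEG + 3 demographic)")
for name in ("relPSD:CZ:delta", "relPSD:CZ:alpha", "Coh:FP1-FP2:alpha",
             "SE:CZ", "PAC:CZ:alpha-gamma", "demo:age"):
    print(f"  {name:22s} {features[name]:8.4f}")
print("\nrelPSD values are fractions of 1-100 Hz power; coherence lies in "
      "[0, 1]; SE is spectral entropy in bits; PAC is the modulation index.")
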