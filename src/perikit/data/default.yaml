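# Default evaluation configuration: published per-landmark sigma calibration,
# k = 2*sigma, detection threshold 0.7, similarity thresholds 0.50:0.05:0.95.
sigma: [0.0895, 0.0816, 0.0193, 0.0196, 0.0209, 0.0273]
k_constant: 2.0
detection_threshold: 0.7
threshold_start: 0.50
threshold_stop: 0.95
threshold_step: 0.05
ranking: keypoint_score
aggregation: mean
severity_thresholds: [10.0, 25.0, 50.0]
severity_labels: [normal, early, moderate, severe]
seed: 0
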