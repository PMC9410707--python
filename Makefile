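PYTHON ?= python

.PHONY: test calibrate acceptance

test:
	$(PYTHON) -m pytest -q tests/

# regenerate the packaged calibrated cohort preset (slow: several minutes)
calibrate:
	$(PYTHON) scripts/calibrate_preset.py --seed 0 --out src/alphadec/presets/hbn_main.yaml

acceptance:
	$(PYTHON) scripts/acceptance.py --seed 1 --out results/acceptance.json
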