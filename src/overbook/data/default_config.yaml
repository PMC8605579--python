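# Default case-study center: four aggregate examination sets over five
# resources, ideal consumer levels K = (36, 36, 24, 4, 2) and maximum
# allowable overage U = K/2.  Prices and original booking limits are
# synthetic placeholders inside the published 20,000-100,000 NTD range.
resources:
  - name: basic
    ideal_consumer_level: 36
    max_allowable_overage: 18
  - name: breast
    ideal_consumer_level: 36
    max_allowable_overage: 18
  - name: gastroenteroscope
    ideal_consumer_level: 24
    max_allowable_overage: 12
  - name: mri
    ideal_consumer_level: 4
    max_allowable_overage: 2
  - name: dwi
    ideal_consumer_level: 2
    max_allowable_overage: 1
sets:
  - name: set1
    price: 25000
    original_booking_limit: 2
    resources: [basic, gastroenteroscope]
  - name: set2
    price: 30000
    original_booking_limit: 22
    resources: [basic, breast, gastroenteroscope]
  - name: set3
    price: 60000
    original_booking_limit: 3
    resources: [basic, mri]
  - name: set4
    price: 80000
    original_booking_limit: 2
    resources: [basic, mri, dwi]
cost_schedule:
  marginal_costs:
    [2500, 2500, 2500, 5000, 5000, 5000, 10000, 10000, 10000, 20000]
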