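age,gender,booking_date,booking_type,examination_date,set_id,price,group_size,cancellation_date
52,female,2019-02-03,online,2019-08-05,set2,30000,1,2019-04-07
52,female,2019-04-07,online,2019-09-03,set2,30000,1,2019-06-02
52,female,2019-06-02,online,2019-10-15,set2,30000,1,
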