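parity,month_in_milk,month_in_pregnancy,cow_value,cow_value_lower_yield,cow_value_health_event
1,2,0,-4,-48,-128
1,3,0,-12,-56,-135
1,4,0,-26,-69,-146
1,5,0,-41,-84,-159
1,6,0,-57,-100,-173
1,7,0,-76,-118,-189
1,8,0,-93,-135,-204
1,9,0,-110,-151,-219
1,10,0,-123,-164,-231
1,3,1,32,-14,-97
1,4,1,28,-17,-100
1,5,1,23,-22,-104
1,6,1,19,-27,-108
1,7,1,15,-31,-111
1,8,1,11,-34,-114
1,9,1,9,-36,-116
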