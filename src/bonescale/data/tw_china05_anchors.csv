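sex,bone_age,sms
male,2.0,79
male,2.5,98
male,3.0,117
male,3.5,123
male,4.0,134
male,5.0,156
male,6.0,180
male,7.0,209
male,8.0,239
male,9.0,262
male,10.0,296
male,11.0,345
male,12.0,426
male,13.0,517
male,14.0,642
male,15.0,835
male,16.0,959
male,16.1,1000
female,2.0,162
female,2.5,174
female,3.0,188
female,3.5,201
female,4.0,210
female,5.0,231
female,6.0,264
female,7.0,306
female,8.0,347
female,9.0,420
female,10.0,496
female,11.0,593
female,12.0,700
female,13.0,861
female,14.0,956
female,15.0,986
female,15.1,1000
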