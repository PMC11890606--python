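# tweetformer emoji short-name table v1
😀	grinning_face
😃	grinning_face_with_big_eyes
😄	grinning_face_with_smiling_eyes
😁	beaming_face_with_smiling_eyes
😂	face_with_tears_of_joy
🤣	rolling_on_the_floor_laughing
😊	smiling_face_with_smiling_eyes
😇	smiling_face_with_halo
🙂	slightly_smiling_face
😉	winking_face
😍	smiling_face_with_heart_eyes
😘	face_blowing_a_kiss
😜	winking_face_with_tongue
🤔	thinking_face
😐	neutral_face
😴	sleeping_face
😷	face_with_medical_mask
🤒	face_with_thermometer
🤕	face_with_head_bandage
🤢	nauseated_face
🤮	face_vomiting
🤧	sneezing_face
😢	crying_face
😭	loudly_crying_face
😡	pouting_face
😠	angry_face
😱	face_screaming_in_fear
😳	flushed_face
😞	disappointed_face
😔	pensive_face
😩	weary_face
😫	tired_face
😅	grinning_face_with_sweat
😬	grimacing_face
🙄	face_with_rolling_eyes
🥵	hot_face
🥶	cold_face
🤷	person_shrugging
🙏	folded_hands
👍	thumbs_up
👎	thumbs_down
👏	clapping_hands
💪	flexed_biceps
🙌	raising_hands
👌	ok_hand
✌	victory_hand
☺	smiling_face
❤	red_heart
💔	broken_heart
💕	two_hearts
💉	syringe
💊	pill
🩺	stethoscope
🌡	thermometer
🏥	hospital
🚑	ambulance
🦠	microbe
🔥	fire
⭐	star
✨	sparkles
🎉	party_popper
💯	hundred_points
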