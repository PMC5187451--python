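level,trigger_or_category,message_id,text
L0,,L0-001,"Quitting is a process, not a single moment. Each day before your quit date is a chance to get ready."
L0,,L0-002,"Make a list of your reasons for quitting and keep it on your phone. Read it when your motivation dips."
L0,,L0-003,"Tell a friend or family member about your quit date. Support makes quitting easier."
L0,,L0-004,"Notice when and where you smoke this week. Knowing your patterns helps you plan around them."
L0,,L0-005,"Mixed feelings about quitting are normal. You can feel unsure and still follow through."
L0,,L0-006,"Plan something to do with your hands for the first smoke-free days: a stress ball, a puzzle, a walk."
L0,,L0-007,"Stock up on substitutes: sugar-free gum, toothpicks, carrot sticks. Small swaps help with cravings."
L0,,L0-008,"If you have quit-smoking medication, start it as directed. Medication can double your chances."
L0,,L0-009,"Think about your hardest smoking trigger and write one plan for handling it without a cigarette."
L0,,L0-010,"The night before your quit date, throw out cigarettes, lighters, and ashtrays. A clean start helps."
L1,,L1-001,"Nice work staying on track. Every smoke-free hour lets your body recover a little more."
L1,,L1-002,"Keep doing what works: stay busy, stay hydrated, and remind yourself why you quit."
L1,,L1-003,"Cravings fade whether or not you smoke. Staying quit means letting them pass."
L1,,L1-004,"Consider telling someone today that you are quitting. Saying it out loud strengthens commitment."
L1,,L1-005,"Money not spent on cigarettes adds up fast. Think of something to put it toward."
L2,stress_affect,L2S-001,"Stress passes whether or not you smoke. Try slow breathing: in for 4 counts, out for 6, ten times."
L2,stress_affect,L2S-002,"Feeling tense or down is a common trigger. Step away from the situation for five minutes if you can."
L2,stress_affect,L2S-003,"A short walk, a glass of water, or calling someone you trust can lower stress without a cigarette."
L2,urge,L2U-001,"Urges peak and fade in a few minutes. Delay, distract, and drink water until this one passes."
L2,urge,L2U-002,"An urge is a signal, not a command. Do something with your hands until it fades."
L2,urge,L2U-003,"Remind yourself: one cigarette would restart the cycle of urges, not end it."
L2,availability,L2A-001,"Cigarettes within reach make slips easy. Get rid of them now or move away from where they are."
L2,availability,L2A-002,"If someone near you is smoking, step away for a few minutes. Distance weakens temptation."
L2,availability,L2A-003,"Ask the people around you not to offer you cigarettes. Most people want to help."
L2,motivation,L2M-001,"Motivation rises and falls. Reread your reasons for quitting; they have not changed."
L2,motivation,L2M-002,"You have already put real work into quitting. Keep that investment by staying quit today."
L2,motivation,L2M-003,"Think of one person who would be proud of you for staying quit. Do the next hour for them."
L3,,L3-001,"A slip is a warning sign, not a failure. Figure out what went wrong and make a stronger plan."
L3,,L3-002,"One slip does not undo your progress. Get rid of any remaining cigarettes and recommit now."
L3,,L3-003,"Many successful quitters slipped along the way. What matters is returning to your quit today."
quit_tips,general_advice,QTG-001,"Set small goals: get through the morning, then the afternoon, then the day."
quit_tips,general_advice,QTG-002,"Change your routine around old smoking times: new route, new seat, new first activity."
quit_tips,benefits,QTB-001,"Within days of quitting, your senses of taste and smell start to recover."
quit_tips,benefits,QTB-002,"Quitting lowers your risk of heart attack, stroke, and cancer, starting now."
quit_tips,coping_urges,QTU-001,"Use the 4 Ds for urges: delay, deep breathe, drink water, do something else."
quit_tips,coping_urges,QTU-002,"Keep your hands and mouth busy: gum, a toothpick, or a cold drink."
quit_tips,coping_stress,QTS-001,"Tense and release each muscle group from your toes to your shoulders."
quit_tips,coping_stress,QTS-002,"Write down what is stressing you and one small step you can take about it."
quit_tips,coping_mood,QTM-001,"Low mood after quitting is common and temporary. Gentle exercise reliably lifts it."
quit_tips,coping_mood,QTM-002,"Do one thing you enjoy today, however small. Reward yourself for staying quit."
medication_tips,varenicline,MTV-001,"Varenicline works best taken after eating with a full glass of water."
medication_tips,varenicline,MTV-002,"Mild nausea on varenicline is common and usually fades; taking it with food helps."
medication_tips,patch,MTP-001,"Apply the nicotine patch to clean, dry, hairless skin and rotate the site daily."
medication_tips,patch,MTP-002,"If you have vivid dreams with the patch, remove it before bed and apply a fresh one in the morning."
medication_tips,gum,MTG-001,"Use nicotine gum with the park-and-chew method: chew until it tingles, then park it in your cheek."
medication_tips,gum,MTG-002,"Avoid food or drink 15 minutes before and during nicotine gum use; acidic drinks block absorption."
medication_tips,bupropion,MTB-001,"Bupropion takes about a week to build up, so it is usually started before the quit date."
medication_tips,bupropion,MTB-002,"Take bupropion doses at least 8 hours apart and avoid alcohol while using it."
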